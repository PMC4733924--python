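"""Core domain types for claims-based progression phenotyping.

The pipeline works on longitudinal administrative-claims event streams.
Each patient has an *index date* (initial stage I-III cancer diagnosis),
an enrollment interval, and a stream of dated claim events abstracted to
semantic categories (no real billing codes).  A chart-review reference
standard records whether and when the patient progressed to distant
metastatic disease.

All dates are integer days since an arbitrary cohort epoch; only
differences between dates are ever interpreted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class TumorType(str, enum.Enum):
    BREAST = "BREAST"
    NSCLC = "NSCLC"
    CRC = "CRC"


class Domain(str, enum.Enum):
    DIAGNOSIS = "DIAGNOSIS"
    PROCEDURE = "PROCEDURE"
    PHARMACY = "PHARMACY"


class Category(str, enum.Enum):
    """Semantic claim-event categories (code lists are out of scope)."""

    SECONDARY_MALIGNANCY_DX = "SECONDARY_MALIGNANCY_DX"
    PRIMARY_MALIGNANCY_DX = "PRIMARY_MALIGNANCY_DX"
    RADIOLOGY = "RADIOLOGY"
    PATHOLOGY = "PATHOLOGY"
    BIOPSY = "BIOPSY"
    SURGERY = "SURGERY"
    RADIATION = "RADIATION"
    AIRWAY_MGMT = "AIRWAY_MGMT"
    PARENTERAL_FEEDING = "PARENTERAL_FEEDING"
    AMBULATORY_AID = "AMBULATORY_AID"
    OPIOID = "OPIOID"
    CHEMO_AGENT = "CHEMO_AGENT"
    CORTICOSTEROID = "CORTICOSTEROID"
    BONE_MED = "BONE_MED"
    IMMUNOTHERAPY = "IMMUNOTHERAPY"
    HORMONAL_THERAPY = "HORMONAL_THERAPY"
    METASTATIC_SPECIFIC_THERAPY = "METASTATIC_SPECIFIC_THERAPY"
    PAIN_DX_BONE = "PAIN_DX_BONE"
    PAIN_DX_SPECIFIC = "PAIN_DX_SPECIFIC"
    PAIN_DX_OTHER = "PAIN_DX_OTHER"
    CONFUSION_DX = "CONFUSION_DX"
    SEIZURE_DX = "SEIZURE_DX"
    FRACTURE_DX = "FRACTURE_DX"
    LUMP_DX = "LUMP_DX"
    DYSPNEA_DX = "DYSPNEA_DX"


class Site(str, enum.Enum):
    PRIMARY_SITE = "PRIMARY_SITE"
    OTHER_SITE = "OTHER_SITE"
    NA = "NA"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


#: Categories for which laterality/site is meaningful (contralateral
#: breast/lung is collapsed into PRIMARY_SITE upstream).
SITED_CATEGORIES = frozenset(
    {Category.RADIOLOGY, Category.BIOPSY, Category.SURGERY, Category.PRIMARY_MALIGNANCY_DX}
)

_DOMAIN_OF_CATEGORY: Mapping[Category, Domain] = {
    Category.SECONDARY_MALIGNANCY_DX: Domain.DIAGNOSIS,
    Category.PRIMARY_MALIGNANCY_DX: Domain.DIAGNOSIS,
    Category.PAIN_DX_BONE: Domain.DIAGNOSIS,
    Category.PAIN_DX_SPECIFIC: Domain.DIAGNOSIS,
    Category.PAIN_DX_OTHER: Domain.DIAGNOSIS,
    Category.CONFUSION_DX: Domain.DIAGNOSIS,
    Category.SEIZURE_DX: Domain.DIAGNOSIS,
    Category.FRACTURE_DX: Domain.DIAGNOSIS,
    Category.LUMP_DX: Domain.DIAGNOSIS,
    Category.DYSPNEA_DX: Domain.DIAGNOSIS,
    Category.RADIOLOGY: Domain.PROCEDURE,
    Category.PATHOLOGY: Domain.PROCEDURE,
    Category.BIOPSY: Domain.PROCEDURE,
    Category.SURGERY: Domain.PROCEDURE,
    Category.RADIATION: Domain.PROCEDURE,
    Category.AIRWAY_MGMT: Domain.PROCEDURE,
    Category.PARENTERAL_FEEDING: Domain.PROCEDURE,
    Category.AMBULATORY_AID: Domain.PROCEDURE,
    Category.OPIOID: Domain.PHARMACY,
    Category.CHEMO_AGENT: Domain.PHARMACY,
    Category.CORTICOSTEROID: Domain.PHARMACY,
    Category.BONE_MED: Domain.PHARMACY,
    Category.IMMUNOTHERAPY: Domain.PHARMACY,
    Category.HORMONAL_THERAPY: Domain.PHARMACY,
    Category.METASTATIC_SPECIFIC_THERAPY: Domain.PHARMACY,
}


def domain_of(category: Category) -> Domain:
    """Claims domain (diagnosis / procedure / pharmacy) of a category."""
    return _DOMAIN_OF_CATEGORY[category]


@dataclass(frozen=True)
class ClaimEvent:
    """One dated claims record, abstracted to a semantic category.

    ``agent_id`` distinguishes individual antineoplastic agents so that
    regimen-change logic can compare agent sets; it is required exactly
    for CHEMO_AGENT events.
    """

    patient_id: str
    date: int
    category: Category
    site: Site = Site.NA
    agent_id: Optional[str] = None
    domain: Domain = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.date < 0:
            raise ValueError(f"event date must be >= 0, got {self.date}")
        if (self.agent_id is not None) != (self.category is Category.CHEMO_AGENT):
            raise ValueError(
                "agent_id must be present iff category is CHEMO_AGENT "
                f"(category={self.category.value}, agent_id={self.agent_id!r})"
            )
        if self.category in SITED_CATEGORIES:
            if self.site is Site.NA:
                raise ValueError(f"{self.category.value} events require an explicit site")
        elif self.site is not Site.NA:
            raise ValueError(f"{self.category.value} events must have site NA")
        if self.domain is None:
            object.__setattr__(self, "domain", domain_of(self.category))
        elif self.domain is not domain_of(self.category):
            raise ValueError(
                f"domain {self.domain.value} inconsistent with category {self.category.value}"
            )


@dataclass
class PatientRecord:
    """A patient's enrollment/index/stage data plus the claim stream."""

    patient_id: str
    tumor_type: TumorType
    age_at_index: float
    sex: Sex
    stage_at_dx: Stage
    index_date: int
    enrollment_start: int
    enrollment_end: int
    events: list[ClaimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.enrollment_start <= self.index_date <= self.enrollment_end):
            raise ValueError(
                f"{self.patient_id}: index date {self.index_date} outside enrollment "
                f"[{self.enrollment_start}, {self.enrollment_end}]"
            )
        if self.tumor_type is TumorType.BREAST and self.sex is not Sex.F:
            raise ValueError(f"{self.patient_id}: breast cohort is restricted to females")
        self.events = sorted(self.events, key=lambda e: e.date)
        for e in self.events:
            if not (self.enrollment_start <= e.date <= self.enrollment_end):
                raise ValueError(
                    f"{self.patient_id}: event at day {e.date} outside enrollment "
                    f"[{self.enrollment_start}, {self.enrollment_end}]"
                )


@dataclass(frozen=True)
class ReferenceOutcome:
    """Chart-review gold standard: progressed to distant metastasis?"""

    patient_id: str
    progressed: bool
    progression_date: Optional[int] = None

    def __post_init__(self) -> None:
        if self.progressed and self.progression_date is None:
            raise ValueError(f"{self.patient_id}: progressed without a progression date")
        if not self.progressed and self.progression_date is not None:
            raise ValueError(f"{self.patient_id}: progression date on a non-progressed patient")


# ---------------------------------------------------------------------------
# Boolean rule trees (candidate algorithms)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """Node of a boolean expression tree over binary indicators.

    Candidate algorithms use "LEAF", "AND" and "OR" nodes only (leaves
    carry the indicator name; internal nodes carry >= 2 children).
    Rules extracted from fitted decision trees may additionally contain
    "NOT" (one child) and the constants "TRUE"/"FALSE", since a tree's
    branch structure need not be monotone in its inputs.
    """

    op: str
    name: Optional[str] = None
    children: tuple["Rule", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "LEAF":
            if not self.name or self.children:
                raise ValueError("LEAF rule needs a name and no children")
        elif self.op in ("AND", "OR"):
            if len(self.children) < 2 or self.name is not None:
                raise ValueError(f"{self.op} rule needs >= 2 children and no name")
        elif self.op == "NOT":
            if len(self.children) != 1 or self.name is not None:
                raise ValueError("NOT rule needs exactly one child and no name")
        elif self.op in ("TRUE", "FALSE"):
            if self.children or self.name is not None:
                raise ValueError(f"{self.op} rule takes no children and no name")
        else:
            raise ValueError(f"unknown rule op {self.op!r}")

    # -- evaluation ---------------------------------------------------------

    def leaves(self) -> frozenset[str]:
        if self.op == "LEAF":
            return frozenset({self.name})  # type: ignore[arg-type]
        if not self.children:
            return frozenset()
        return frozenset().union(*(c.leaves() for c in self.children))

    def evaluate(self, indicators: Mapping[str, bool]) -> bool:
        if self.op == "LEAF":
            return bool(indicators[self.name])  # type: ignore[index]
        if self.op == "TRUE":
            return True
        if self.op == "FALSE":
            return False
        if self.op == "NOT":
            return not self.children[0].evaluate(indicators)
        values = (c.evaluate(indicators) for c in self.children)
        return all(values) if self.op == "AND" else any(values)

    def is_monotone_form(self) -> bool:
        """True when built from LEAF/AND/OR only (detection dates defined)."""
        if self.op == "LEAF":
            return True
        if self.op in ("AND", "OR"):
            return all(c.is_monotone_form() for c in self.children)
        return False

    def detection_date(self, first_trigger: Mapping[str, Optional[int]]) -> Optional[int]:
        """Earliest day at which the rule is satisfied.

        AND nodes are satisfied once the latest child is (max of child
        dates); OR nodes at the earliest satisfied child (min).  Only
        defined for monotone (LEAF/AND/OR) rules: absence of a claim
        has no date.
        """
        if self.op == "LEAF":
            return first_trigger.get(self.name)  # type: ignore[arg-type]
        if self.op in ("NOT", "TRUE", "FALSE"):
            raise ValueError(f"detection dates are undefined for {self.op} nodes")
        dates = [c.detection_date(first_trigger) for c in self.children]
        if self.op == "AND":
            if any(d is None for d in dates):
                return None
            return max(d for d in dates if d is not None)
        satisfied = [d for d in dates if d is not None]
        return min(satisfied) if satisfied else None

    def truth_table(self, variables: Sequence[str]) -> tuple[bool, ...]:
        """Rule output for every assignment of ``variables`` (lexicographic
        over bit patterns, variable 0 most significant)."""
        k = len(variables)
        if k > 16:
            raise ValueError("truth table limited to 16 variables")
        out = []
        for bits in range(2**k):
            assign = {v: bool((bits >> (k - 1 - i)) & 1) for i, v in enumerate(variables)}
            out.append(self.evaluate(assign))
        return tuple(out)

    # -- construction / serialization --------------------------------------

    def to_json(self) -> object:
        if self.op == "LEAF":
            return self.name
        if self.op in ("TRUE", "FALSE"):
            return {"const": self.op == "TRUE"}
        return {self.op.lower(): [c.to_json() for c in self.children]}

    @staticmethod
    def from_json(obj: object) -> "Rule":
        if isinstance(obj, str):
            return leaf(obj)
        if isinstance(obj, dict) and len(obj) == 1:
            (op, kids), = obj.items()
            if op == "const":
                return Rule("TRUE" if kids else "FALSE")
            return Rule(op.upper(), children=tuple(Rule.from_json(k) for k in kids))
        raise ValueError(f"malformed rule JSON: {obj!r}")

    def __str__(self) -> str:
        if self.op == "LEAF":
            return str(self.name)
        if self.op in ("TRUE", "FALSE"):
            return self.op
        if self.op == "NOT":
            return f"NOT {self.children[0]}"
        sep = " AND " if self.op == "AND" else " OR "
        return "(" + sep.join(str(c) for c in self.children) + ")"


def leaf(name: str) -> Rule:
    return Rule("LEAF", name=name)


def and_(*children: Rule) -> Rule:
    return Rule("AND", children=tuple(children))


def or_(*children: Rule) -> Rule:
    return Rule("OR", children=tuple(children))


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named candidate algorithm: a boolean rule over indicators."""

    name: str
    tumor_type: TumorType
    rule: Rule


# ---------------------------------------------------------------------------
# Performance accounting
# ---------------------------------------------------------------------------


def _round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMeasures:
    """Sensitivity/specificity/PPV/NPV in percent, one decimal.

    A measure whose denominator is zero is undefined and reported as
    ``None`` -- never coerced to 0.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @staticmethod
    def from_confusion(cm: ConfusionMatrix) -> "PerformanceMeasures":
        def rate(num: int, den: int) -> Optional[float]:
            if den == 0:
                return None
            return _round_half_away(100.0 * num / den, 1)

        return PerformanceMeasures(
            sensitivity=rate(cm.tp, cm.tp + cm.fn),
            specificity=rate(cm.tn, cm.tn + cm.fp),
            ppv=rate(cm.tp, cm.tp + cm.fp),
            npv=rate(cm.tn, cm.tn + cm.fn),
        )


def validate_cohort(
    patients: Iterable[PatientRecord], outcomes: Iterable[ReferenceOutcome]
) -> None:
    """Cross-record invariant sweep; raises on the first violation."""
    outcome_by_id = {o.patient_id: o for o in outcomes}
    for p in patients:
        o = outcome_by_id.get(p.patient_id)
        if o is None:
            raise ValueError(f"no outcome record for patient {p.patient_id}")
        if o.progressed and o.progression_date is not None:
            if o.progression_date <= p.index_date:
                raise ValueError(
                    f"{p.patient_id}: progression date {o.progression_date} "
                    f"not after index {p.index_date}"
                )
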