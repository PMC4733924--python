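"""Anchor-lag construction of binary progression indicators from claims.

The temporal template: an *anchor* is any radiology or pathology claim at
least ``anchor_min_days_after_index`` days (default 60) after the index
date; an indicator fires when a qualifying claim element falls within
``element_lag`` days (default 30) after some anchor.  Both boundaries are
inclusive: an anchor at exactly index+60 qualifies, and an element at
exactly anchor+30 qualifies.

Indicator modes
---------------
PRESENCE
    Any matching event inside an anchor window.
INITIATION
    As PRESENCE, but no event of the same category may occur at any
    earlier date (treatment-naive start).
CHEMO_CHANGE / MULTI_TO_SINGLE
    Regimen logic over CHEMO_AGENT events: consecutive dispensings no
    more than ``chemo_gap_for_new_regimen`` days apart form one regimen,
    whose agent set is the distinct agents seen within the regimen's
    first ``regimen_window`` days.  A change fires when a regimen whose
    start lies inside an anchor window carries an agent set different
    from the immediately preceding regimen's; the multidrug-to-single
    variant additionally requires the prior set to have >= 2 agents and
    the new set exactly one.
METASTATIC_SPECIFIC
    Initiation semantics applied to the metastatic-specific-therapy
    drug class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .types import (
    Category,
    ClaimEvent,
    PatientRecord,
    ReferenceOutcome,
    Site,
    TumorType,
)

#: Delayed anchor windows examined in sensitivity analyses.
STANDARD_ANCHOR_WINDOWS = (60, 90, 120, 180, 365)

#: Name of the anchor-presence pseudo-indicator (the rule's initial element).
ANCHOR_INDICATOR = "radiology_pathology_claim"


@dataclass(frozen=True)
class FeatureConfig:
    anchor_min_days_after_index: int = 60
    element_lag: int = 30
    regimen_window: int = 90
    chemo_gap_for_new_regimen: int = 60
    allow_nonstandard_window: bool = False

    def __post_init__(self) -> None:
        if self.element_lag <= 0:
            raise ValueError("element_lag must be positive")
        if min(self.anchor_min_days_after_index, self.regimen_window,
               self.chemo_gap_for_new_regimen) < 0:
            raise ValueError("window parameters must be non-negative")
        if (self.anchor_min_days_after_index not in STANDARD_ANCHOR_WINDOWS
                and not self.allow_nonstandard_window):
            raise ValueError(
                f"anchor window {self.anchor_min_days_after_index} is not one of "
                f"{STANDARD_ANCHOR_WINDOWS}; set allow_nonstandard_window=True to override"
            )


class Mode(str, enum.Enum):
    PRESENCE = "PRESENCE"
    INITIATION = "INITIATION"
    CHEMO_CHANGE = "CHEMO_CHANGE"
    MULTI_TO_SINGLE = "MULTI_TO_SINGLE"
    METASTATIC_SPECIFIC = "METASTATIC_SPECIFIC"


@dataclass(frozen=True)
class IndicatorDef:
    """One candidate progression indicator."""

    name: str
    tumor_types: frozenset[TumorType]
    mode: Mode
    category: Optional[Category] = None
    site: Optional[Site] = None  # restrict matcher to one site when set

    def matches(self, event: ClaimEvent) -> bool:
        if self.category is None or event.category is not self.category:
            return False
        return self.site is None or event.site is self.site


_ALL = frozenset({TumorType.BREAST, TumorType.NSCLC, TumorType.CRC})
_B = frozenset({TumorType.BREAST})
_N = frozenset({TumorType.NSCLC})
_BN = frozenset({TumorType.BREAST, TumorType.NSCLC})


def _presence(name: str, tt: frozenset, cat: Category, site: Optional[Site] = None) -> IndicatorDef:
    return IndicatorDef(name, tt, Mode.PRESENCE, cat, site)


#: The full indicator catalogue, in report order.  Tumor-type
#: restrictions mirror which indicators are clinically meaningful for
#: each cancer (e.g. airway management and parenteral feeding only for
#: lung; hormonal/immunotherapy initiation only for breast).
INDICATOR_CATALOGUE: tuple[IndicatorDef, ...] = (
    _presence("secondary_malignancy", _ALL, Category.SECONDARY_MALIGNANCY_DX),
    _presence("different_site_malignancy", _ALL, Category.PRIMARY_MALIGNANCY_DX, Site.OTHER_SITE),
    _presence("radiology_non_primary_site", _ALL, Category.RADIOLOGY, Site.OTHER_SITE),
    _presence("biopsy_non_primary_site", _ALL, Category.BIOPSY, Site.OTHER_SITE),
    _presence("more_invasive_surgery", _ALL, Category.SURGERY, Site.PRIMARY_SITE),
    _presence("surgery_non_primary_site", _ALL, Category.SURGERY, Site.OTHER_SITE),
    _presence("pain_medication", _ALL, Category.OPIOID),
    _presence("bone_disease_medication", _ALL, Category.BONE_MED),
    _presence("corticosteroids", _ALL, Category.CORTICOSTEROID),
    _presence("ambulatory_aids", _ALL, Category.AMBULATORY_AID),
    _presence("radiation_any", _ALL, Category.RADIATION),
    _presence("airway_management", _N, Category.AIRWAY_MGMT),
    _presence("feeding", _N, Category.PARENTERAL_FEEDING),
    IndicatorDef("initiation_of_radiation", _ALL, Mode.INITIATION, Category.RADIATION),
    IndicatorDef("initiation_of_hormonal_therapy", _B, Mode.INITIATION, Category.HORMONAL_THERAPY),
    IndicatorDef("initiation_of_immunotherapy", _B, Mode.INITIATION, Category.IMMUNOTHERAPY),
    IndicatorDef("change_in_chemotherapy", _ALL, Mode.CHEMO_CHANGE),
    IndicatorDef("initiation_of_metastatic_specific_therapy", _ALL, Mode.METASTATIC_SPECIFIC,
                 Category.METASTATIC_SPECIFIC_THERAPY),
    IndicatorDef("multidrug_to_single_agent", _BN, Mode.MULTI_TO_SINGLE),
    _presence("bone_pain", _ALL, Category.PAIN_DX_BONE),
    _presence("specific_pain", _B, Category.PAIN_DX_SPECIFIC),
    _presence("other_pain", _B, Category.PAIN_DX_OTHER),
    _presence("confusion", _ALL, Category.CONFUSION_DX),
    _presence("seizures", _ALL, Category.SEIZURE_DX),
    _presence("fractures", _ALL, Category.FRACTURE_DX),
    _presence("lump_swelling", _B, Category.LUMP_DX),
    _presence("shortness_of_breath", _B, Category.DYSPNEA_DX),
)

_BY_NAME = {d.name: d for d in INDICATOR_CATALOGUE}


def indicator(name: str) -> IndicatorDef:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown indicator {name!r}") from None


def indicators_for(tumor_type: TumorType) -> tuple[IndicatorDef, ...]:
    """Catalogue subset applicable to one tumor type, in report order."""
    return tuple(d for d in INDICATOR_CATALOGUE if tumor_type in d.tumor_types)


@dataclass
class FeatureVector:
    patient_id: str
    anchor_dates: list[int]
    indicators: dict[str, bool] = field(default_factory=dict)
    first_trigger: dict[str, Optional[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Window machinery
# ---------------------------------------------------------------------------


def anchor_dates(patient: PatientRecord, config: FeatureConfig) -> list[int]:
    """Dates of radiology/pathology claims >= index + anchor window.

    Duplicates are retained; the list is ascending.
    """
    cutoff = patient.index_date + config.anchor_min_days_after_index
    return sorted(
        e.date
        for e in patient.events
        if e.category in (Category.RADIOLOGY, Category.PATHOLOGY) and e.date >= cutoff
    )


def _in_some_window(date: int, anchors: Sequence[int], lag: int) -> bool:
    # anchors ascending; an element may pair with ANY anchor
    return any(a <= date <= a + lag for a in anchors)


def element_triggered(
    patient: PatientRecord,
    ind: IndicatorDef,
    anchors: Sequence[int],
    config: FeatureConfig,
) -> tuple[bool, Optional[int]]:
    """PRESENCE evaluation: earliest matching event inside an anchor window."""
    _check_applicable(patient, ind)
    for e in patient.events:  # ascending by date
        if ind.matches(e) and _in_some_window(e.date, anchors, config.element_lag):
            return True, e.date
    return False, None


def initiation_triggered(
    patient: PatientRecord,
    ind: IndicatorDef,
    anchors: Sequence[int],
    config: FeatureConfig,
) -> tuple[bool, Optional[int]]:
    """INITIATION evaluation: as PRESENCE, but treatment-naive.

    No event of the same category may occur strictly before the
    triggering date.  Because events are date-ascending, only the
    first matching-category event can qualify.
    """
    _check_applicable(patient, ind)
    for e in patient.events:
        if e.category is ind.category:
            if ind.matches(e) and _in_some_window(e.date, anchors, config.element_lag):
                return True, e.date
            return False, None  # an earlier same-category event blocks initiation
    return False, None


@dataclass(frozen=True)
class _Regimen:
    start: int
    agents: frozenset[str]


def chemo_regimens(patient: PatientRecord, config: FeatureConfig) -> list[_Regimen]:
    """Partition CHEMO_AGENT events into regimens.

    A new regimen starts when the gap from the previous chemo event
    exceeds ``chemo_gap_for_new_regimen`` days; the agent set is taken
    from the regimen's first ``regimen_window`` days.
    """
    chemo = [e for e in patient.events if e.category is Category.CHEMO_AGENT]
    regimens: list[_Regimen] = []
    group: list[ClaimEvent] = []
    for e in chemo:
        if group and e.date - group[-1].date > config.chemo_gap_for_new_regimen:
            regimens.append(_close_regimen(group, config))
            group = []
        group.append(e)
    if group:
        regimens.append(_close_regimen(group, config))
    return regimens


def _close_regimen(group: list[ClaimEvent], config: FeatureConfig) -> _Regimen:
    start = group[0].date
    agents = frozenset(
        e.agent_id for e in group if e.date <= start + config.regimen_window
    )
    return _Regimen(start=start, agents=agents)  # type: ignore[arg-type]


def chemo_change_triggered(
    patient: PatientRecord,
    anchors: Sequence[int],
    config: FeatureConfig,
    multidrug_to_single: bool = False,
) -> tuple[bool, Optional[int]]:
    """Regimen-change evaluation (earliest qualifying regimen start)."""
    regimens = chemo_regimens(patient, config)
    for prev, cur in zip(regimens, regimens[1:]):
        if not _in_some_window(cur.start, anchors, config.element_lag):
            continue
        if cur.agents == prev.agents:
            continue
        if multidrug_to_single and not (len(prev.agents) >= 2 and len(cur.agents) == 1):
            continue
        return True, cur.start
    return False, None


def _check_applicable(patient: PatientRecord, ind: IndicatorDef) -> None:
    if patient.tumor_type not in ind.tumor_types:
        raise ValueError(
            f"indicator {ind.name!r} is not defined for tumor type "
            f"{patient.tumor_type.value}"
        )


_EVALUATORS: dict[Mode, Callable] = {}


def evaluate_indicator(
    patient: PatientRecord,
    ind: IndicatorDef,
    anchors: Sequence[int],
    config: FeatureConfig,
) -> tuple[bool, Optional[int]]:
    _check_applicable(patient, ind)
    if ind.mode is Mode.PRESENCE:
        return element_triggered(patient, ind, anchors, config)
    if ind.mode in (Mode.INITIATION, Mode.METASTATIC_SPECIFIC):
        return initiation_triggered(patient, ind, anchors, config)
    if ind.mode is Mode.CHEMO_CHANGE:
        return chemo_change_triggered(patient, anchors, config)
    if ind.mode is Mode.MULTI_TO_SINGLE:
        return chemo_change_triggered(patient, anchors, config, multidrug_to_single=True)
    raise AssertionError(f"unhandled mode {ind.mode}")


def extract_features(patient: PatientRecord, config: FeatureConfig | None = None) -> FeatureVector:
    """Evaluate every applicable indicator for one patient.

    Also emits the anchor-presence pseudo-indicator (first trigger =
    earliest anchor date).
    """
    config = config or FeatureConfig()
    anchors = anchor_dates(patient, config)
    fv = FeatureVector(patient_id=patient.patient_id, anchor_dates=anchors)
    fv.indicators[ANCHOR_INDICATOR] = bool(anchors)
    fv.first_trigger[ANCHOR_INDICATOR] = anchors[0] if anchors else None
    for ind in indicators_for(patient.tumor_type):
        hit, day = evaluate_indicator(patient, ind, anchors, config)
        fv.indicators[ind.name] = hit
        fv.first_trigger[ind.name] = day
    return fv


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------


def features_frame(
    patients: Iterable[PatientRecord], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Patients x indicators 0/1 matrix (anchor pseudo-indicator included)."""
    rows = []
    for p in patients:
        fv = extract_features(p, config)
        rows.append({"patient_id": p.patient_id, **{k: int(v) for k, v in fv.indicators.items()}})
    return pd.DataFrame(rows).set_index("patient_id")


def feature_matrix(
    patients: Sequence[PatientRecord],
    outcomes: Sequence[ReferenceOutcome],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Indicator counts and percents stratified by progression status.

    One row per applicable indicator (anchor pseudo-indicator first),
    mirroring the conditional-prevalence layout of a validation report.
    """
    if not patients:
        raise ValueError("empty cohort")
    progressed_ids = {o.patient_id for o in outcomes if o.progressed}
    frame = features_frame(patients, config)
    is_prog = frame.index.to_series().isin(progressed_ids)
    n_prog = int(is_prog.sum())
    n_not = len(frame) - n_prog

    records = []
    for col in frame.columns:
        k_not = int(frame.loc[~is_prog, col].sum())
        k_prog = int(frame.loc[is_prog, col].sum())
        records.append(
            {
                "indicator": col,
                "n_not_progressed": k_not,
                "pct_not_progressed": 100.0 * k_not / n_not if n_not else 0.0,
                "n_progressed": k_prog,
                "pct_progressed": 100.0 * k_prog / n_prog if n_prog else 0.0,
            }
        )
    out = pd.DataFrame(records).set_index("indicator")
    out.attrs["n_progressed"] = n_prog
    out.attrs["n_not_progressed"] = n_not
    return out


def apply_delayed_window_exclusion(
    patients: Sequence[PatientRecord],
    outcomes: Sequence[ReferenceOutcome],
    config: FeatureConfig,
    min_followup_days: int = 365,
) -> tuple[list[PatientRecord], list[ReferenceOutcome]]:
    """Extra exclusion for delayed anchor windows (> 60 days).

    Delayed-window sensitivity analyses drop patients who progressed or
    were lost to follow-up within a year of the index date, since a
    delayed anchor cannot capture their events.  Applied uniformly for
    every window above the 60-day default.
    """
    if config.anchor_min_days_after_index <= 60:
        return list(patients), list(outcomes)
    by_id = {o.patient_id: o for o in outcomes}
    kept_p, kept_o = [], []
    for p in patients:
        o = by_id[p.patient_id]
        horizon = p.index_date + min_followup_days
        if p.enrollment_end < horizon:
            continue
        if o.progressed and o.progression_date is not None and o.progression_date < horizon:
            continue
        kept_p.append(p)
        kept_o.append(o)
    return kept_p, kept_o


def with_window(config: FeatureConfig, anchor_min: int) -> FeatureConfig:
    """Convenience: same config with a different anchor window."""
    return replace(config, anchor_min_days_after_index=anchor_min)
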