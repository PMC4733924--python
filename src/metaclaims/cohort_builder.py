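"""Eligibility screening for the analysis cohort.

Inclusion requires adults (>= 18 years at index) with stage I-III
disease, enrollment covering the index date, and at least 90 days of
continuous enrollment after it.  Patients with a second primary tumor
on or before the index date, or with any evidence of metastatic disease
(a secondary-malignancy claim or reference-standard progression) before
or within 60 days after the index date, are excluded: metastasis that
early is considered part of the initial work-up, not progression.

Boundary semantics, applied everywhere: "fewer than 90 days" excludes
``enrollment_end - index_date <= 89`` (day 90 survives); "within 60
days" includes day 60 exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .types import Category, PatientRecord, ReferenceOutcome, Site, Stage


class ExclusionReason(str, enum.Enum):
    """Exclusion criteria in precedence order (first failing wins)."""

    UNDERAGE = "UNDERAGE"
    STAGE_IV_AT_DX = "STAGE_IV_AT_DX"
    SECOND_PRIMARY_AT_INDEX = "SECOND_PRIMARY_AT_INDEX"
    SHORT_ENROLLMENT = "SHORT_ENROLLMENT"
    EARLY_METASTASIS = "EARLY_METASTASIS"
    NOT_ENROLLED_AT_INDEX = "NOT_ENROLLED_AT_INDEX"


@dataclass(frozen=True)
class EligibilityConfig:
    min_age: float = 18.0
    min_post_index_enrollment: int = 90
    metastatic_washout: int = 60
    allowed_stages: frozenset[Stage] = frozenset({Stage.I, Stage.II, Stage.III})

    def __post_init__(self) -> None:
        if self.min_age < 0 or self.min_post_index_enrollment < 0 or self.metastatic_washout < 0:
            raise ValueError("eligibility thresholds must be non-negative")


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    reason: ExclusionReason
    #: every criterion the patient failed, in precedence order
    all_failed: tuple[ExclusionReason, ...] = ()


def _failed_criteria(
    patient: PatientRecord,
    outcome: ReferenceOutcome,
    config: EligibilityConfig,
) -> list[ExclusionReason]:
    failed: list[ExclusionReason] = []
    if patient.age_at_index < config.min_age:
        failed.append(ExclusionReason.UNDERAGE)
    if patient.stage_at_dx not in config.allowed_stages:
        failed.append(ExclusionReason.STAGE_IV_AT_DX)
    if any(
        e.category is Category.PRIMARY_MALIGNANCY_DX
        and e.site is Site.OTHER_SITE  # own-site dx is the index cancer itself
        and e.date <= patient.index_date
        for e in patient.events
    ):
        failed.append(ExclusionReason.SECOND_PRIMARY_AT_INDEX)
    if patient.enrollment_end - patient.index_date < config.min_post_index_enrollment:
        failed.append(ExclusionReason.SHORT_ENROLLMENT)
    washout_end = patient.index_date + config.metastatic_washout
    claims_met = any(
        e.category is Category.SECONDARY_MALIGNANCY_DX and e.date <= washout_end
        for e in patient.events
    )
    reference_met = (
        outcome.progressed
        and outcome.progression_date is not None
        and outcome.progression_date <= washout_end
    )
    if claims_met or reference_met:
        failed.append(ExclusionReason.EARLY_METASTASIS)
    if not (patient.enrollment_start <= patient.index_date <= patient.enrollment_end):
        failed.append(ExclusionReason.NOT_ENROLLED_AT_INDEX)
    return failed


def apply_eligibility(
    patients: Sequence[PatientRecord],
    outcomes: Sequence[ReferenceOutcome],
    config: Optional[EligibilityConfig] = None,
) -> tuple[list[PatientRecord], list[ExclusionRecord]]:
    """Partition a candidate cohort into eligible patients and exclusions.

    Input order is preserved; each excluded patient gets one record
    whose ``reason`` is the first failed criterion in precedence order
    and whose ``all_failed`` lists every failed criterion.
    """
    config = config or EligibilityConfig()
    outcome_by_id = {o.patient_id: o for o in outcomes}
    eligible: list[PatientRecord] = []
    exclusions: list[ExclusionRecord] = []
    for p in patients:
        outcome = outcome_by_id.get(p.patient_id)
        if outcome is None:
            raise ValueError(f"no reference outcome for patient {p.patient_id}")
        failed = _failed_criteria(p, outcome, config)
        if failed:
            exclusions.append(ExclusionRecord(p.patient_id, failed[0], tuple(failed)))
        else:
            eligible.append(p)
    return eligible, exclusions


def cohort_summary(
    eligible: Sequence[PatientRecord],
    outcomes: Sequence[ReferenceOutcome],
) -> pd.DataFrame:
    """Per-tumor-type descriptive table: n, age, sex, progression."""
    if not eligible:
        raise ValueError("empty cohort")
    progressed_ids = {o.patient_id for o in outcomes if o.progressed}
    frame = pd.DataFrame(
        {
            "tumor_type": [p.tumor_type.value for p in eligible],
            "age": [p.age_at_index for p in eligible],
            "male": [p.sex.value == "M" for p in eligible],
            "progressed": [p.patient_id in progressed_ids for p in eligible],
        }
    )
    rows = []
    for tt, grp in frame.groupby("tumor_type", sort=False):
        n = len(grp)
        k = int(grp["progressed"].sum())
        rows.append(
            {
                "tumor_type": tt,
                "n": n,
                "age_median": float(grp["age"].median()),
                "age_q1": float(grp["age"].quantile(0.25)),
                "age_q3": float(grp["age"].quantile(0.75)),
                "n_male": int(grp["male"].sum()),
                "n_female": n - int(grp["male"].sum()),
                "n_progressed": k,
                "pct_progressed": 100.0 * k / n,
            }
        )
    return pd.DataFrame(rows).set_index("tumor_type")
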