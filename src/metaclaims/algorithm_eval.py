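"""Candidate-algorithm evaluation against the chart-review standard.

An algorithm is a boolean rule tree over the binary indicators.  The
built-in models are the published candidate algorithms per tumor type
(a lone secondary-malignancy code, plus the two- and three-variable
combinations).  Evaluation applies the timing match: a positive call in
a progressed patient counts as a true positive only when its detection
date falls within ``match_window`` days (default 90) on either side of
the chart-review progression date; a mistimed positive is counted as a
false negative by default (detection failed at the required time),
configurable to false-positive-style accounting for sensitivity
analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .feature_engine import FeatureVector
from .types import (
    AlgorithmSpec,
    ConfusionMatrix,
    PerformanceMeasures,
    ReferenceOutcome,
    Rule,
    TumorType,
    _round_half_away,
    and_,
    leaf,
    or_,
)


@dataclass(frozen=True)
class MatchConfig:
    match_window: int = 90
    #: when True, a mistimed positive in a progressed patient is counted
    #: FP-style (call rejected AND a spurious positive); default counts it FN
    mistimed_as_fp: bool = False

    def __post_init__(self) -> None:
        if self.match_window < 0:
            raise ValueError("match_window must be non-negative")


class Cell(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"


def builtin_algorithms(tumor_type: TumorType) -> list[AlgorithmSpec]:
    """The published candidate models for one tumor type.

    Breast: M1 secondary malignancy; M2 secondary OR different-site
    malignancy; M3 secondary AND (different-site OR initiation of
    immunotherapy).  NSCLC: M1, M2 as breast; M3 secondary OR
    (different-site AND chemotherapy change).  CRC: M1; M2 secondary OR
    chemotherapy change.
    """
    sec = leaf("secondary_malignancy")
    diff = leaf("different_site_malignancy")
    if tumor_type is TumorType.BREAST:
        rules = [
            ("model_1", sec),
            ("model_2", or_(sec, diff)),
            ("model_3", and_(sec, or_(diff, leaf("initiation_of_immunotherapy")))),
        ]
    elif tumor_type is TumorType.NSCLC:
        rules = [
            ("model_1", sec),
            ("model_2", or_(sec, diff)),
            ("model_3", or_(sec, and_(diff, leaf("change_in_chemotherapy")))),
        ]
    elif tumor_type is TumorType.CRC:
        rules = [
            ("model_1", sec),
            ("model_2", or_(sec, leaf("change_in_chemotherapy"))),
        ]
    else:
        raise ValueError(f"unknown tumor type {tumor_type!r}")
    return [AlgorithmSpec(name, tumor_type, rule) for name, rule in rules]


def apply_algorithm(
    spec: AlgorithmSpec, fv: FeatureVector
) -> tuple[bool, Optional[int]]:
    """Evaluate one rule on one feature vector.

    Returns (positive, detection date): the earliest day at which the
    rule is satisfied, combining first-trigger dates with max over AND
    children and min over satisfied OR children.
    """
    missing = spec.rule.leaves() - set(fv.indicators)
    if missing:
        raise ValueError(
            f"feature vector for {fv.patient_id} lacks indicators {sorted(missing)}"
        )
    positive = spec.rule.evaluate(fv.indicators)
    date = spec.rule.detection_date(fv.first_trigger) if positive else None
    return positive, date


def classify(
    positive: bool,
    detection_date: Optional[int],
    outcome: ReferenceOutcome,
    match: Optional[MatchConfig] = None,
) -> Cell:
    """Assign one patient to a 2x2 cell under the timing match."""
    match = match or MatchConfig()
    if positive and detection_date is None:
        raise ValueError(f"{outcome.patient_id}: positive call without a detection date")
    if outcome.progressed:
        assert outcome.progression_date is not None
        if positive and abs(detection_date - outcome.progression_date) <= match.match_window:  # type: ignore[operator]
            return Cell.TP
        if positive and match.mistimed_as_fp:
            return Cell.FP
        return Cell.FN
    return Cell.FP if positive else Cell.TN


def evaluate(
    features: Mapping[str, FeatureVector] | Sequence[FeatureVector],
    outcomes: Sequence[ReferenceOutcome],
    spec: AlgorithmSpec,
    match: Optional[MatchConfig] = None,
) -> tuple[ConfusionMatrix, PerformanceMeasures]:
    """Aggregate per-patient classification into a 2x2 table and metrics."""
    if not isinstance(features, Mapping):
        features = {fv.patient_id: fv for fv in features}
    if not features:
        raise ValueError("empty cohort")
    match = match or MatchConfig()
    cells = {c: 0 for c in Cell}
    for outcome in outcomes:
        fv = features.get(outcome.patient_id)
        if fv is None:
            raise ValueError(f"no feature vector for patient {outcome.patient_id}")
        positive, date = apply_algorithm(spec, fv)
        cells[classify(positive, date, outcome, match)] += 1
    cm = ConfusionMatrix(tp=cells[Cell.TP], fp=cells[Cell.FP],
                         fn=cells[Cell.FN], tn=cells[Cell.TN])
    return cm, PerformanceMeasures.from_confusion(cm)


def reconstruct_confusion(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Recover integer 2x2 cells from marginals plus printed rates.

    TP = round(sensitivity * n_pos / 100) and TN = round(specificity *
    n_neg / 100), rounding half away from zero; the remaining cells are
    the complements.  Used to turn published cohort sizes and rates
    back into the underlying table.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("marginals must be non-negative")
    if not (0.0 <= sensitivity <= 100.0 and 0.0 <= specificity <= 100.0):
        raise ValueError("rates must lie in [0, 100]")
    tp = int(_round_half_away(sensitivity * n_pos / 100.0))
    tn = int(_round_half_away(specificity * n_neg / 100.0))
    fn, fp = n_pos - tp, n_neg - tn
    if fn < 0 or fp < 0:
        raise ValueError("rates imply negative complement cells")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluation_report(
    features: Mapping[str, FeatureVector] | Sequence[FeatureVector],
    outcomes: Sequence[ReferenceOutcome],
    specs: Sequence[AlgorithmSpec],
    match: Optional[MatchConfig] = None,
) -> pd.DataFrame:
    """One row per algorithm: 2x2 cells plus the four measures."""
    rows = []
    for spec in specs:
        cm, pm = evaluate(features, outcomes, spec, match)
        rows.append(
            {
                "algorithm": spec.name,
                "tumor_type": spec.tumor_type.value,
                "rule": str(spec.rule),
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                "sensitivity": pm.sensitivity,
                "specificity": pm.specificity,
                "ppv": pm.ppv,
                "npv": pm.npv,
            }
        )
    return pd.DataFrame(rows).set_index(["tumor_type", "algorithm"])
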