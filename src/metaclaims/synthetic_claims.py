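"""Synthetic administrative-claims cohorts for progression phenotyping.

The real study population (a single-system health plan) is not publicly
available, so this module generates cohorts with the same statistical
skeleton: three tumor-type cohorts with their published sizes and
progression prevalences, per-indicator prevalences conditional on
progression status, log-normal enrollment durations calibrated to the
published median/IQR, and anchor-claim streams.  Positive indicators are
realised as concrete claim patterns (an anchor radiology/pathology claim
followed by the qualifying element within the 30-day lag) so that the
feature engine recovers exactly the drawn indicator set.

A second generator builds small deterministic fixtures that realise a
requested confusion matrix end-to-end, used to reproduce published
worked examples exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .feature_engine import IndicatorDef, Mode, indicator, indicators_for
from .types import (
    AlgorithmSpec,
    Category,
    ClaimEvent,
    PatientRecord,
    ReferenceOutcome,
    Sex,
    Site,
    Stage,
    TumorType,
)

DAYS_PER_MONTH = 30.4375
_RETRY_CAP = 100

# ---------------------------------------------------------------------------
# Published cohort profiles (conditional indicator prevalences)
# ---------------------------------------------------------------------------

# (count among progressed, count among non-progressed); None = indicator
# not defined for the tumor type.
_PROFILE_COUNTS: dict[TumorType, dict] = {
    TumorType.BREAST: {
        "n": 502,
        "n_progressed": 17,
        "anchor": (17, 481),
        "enrollment_months": (35.7, 20.0, 59.9),  # median, q1, q3
        "age_mean_sd": (61.4, 13.3),
        "male_fraction": 0.0,
        "indicators": {
            "secondary_malignancy": (16, 68),
            "different_site_malignancy": (12, 55),
            "radiology_non_primary_site": (17, 387),
            "biopsy_non_primary_site": (10, 77),
            "more_invasive_surgery": (1, 26),
            "surgery_non_primary_site": (3, 67),
            "pain_medication": (10, 250),
            "bone_disease_medication": (2, 60),
            "corticosteroids": (15, 284),
            "ambulatory_aids": (4, 39),
            "radiation_any": (14, 358),
            "initiation_of_radiation": (9, 138),
            "initiation_of_hormonal_therapy": (4, 189),
            "initiation_of_immunotherapy": (8, 28),
            "change_in_chemotherapy": (12, 154),
            "initiation_of_metastatic_specific_therapy": (8, 93),
            "multidrug_to_single_agent": (6, 36),
            "bone_pain": (2, 54),
            "specific_pain": (9, 128),
            "other_pain": (1, 5),
            "confusion": (0, 0),
            "seizures": (0, 0),
            "fractures": (1, 41),
            "lump_swelling": (2, 21),
            "shortness_of_breath": (5, 64),
        },
    },
    TumorType.NSCLC: {
        "n": 236,
        "n_progressed": 61,
        "anchor": (61, 171),
        "enrollment_months": (17.6, 8.6, 33.1),
        "age_mean_sd": (70.7, 9.3),
        "male_fraction": 0.568,
        "indicators": {
            "secondary_malignancy": (53, 41),
            "different_site_malignancy": (36, 35),
            "radiology_non_primary_site": (60, 157),
            "biopsy_non_primary_site": (15, 27),
            "more_invasive_surgery": (0, 2),
            "surgery_non_primary_site": (6, 11),
            "pain_medication": (47, 88),
            "bone_disease_medication": (5, 0),
            "corticosteroids": (51, 110),
            "ambulatory_aids": (16, 24),
            "radiation_any": (43, 74),
            "airway_management": (5, 3),
            "feeding": (0, 1),
            "initiation_of_radiation": (26, 26),
            "change_in_chemotherapy": (38, 61),
            "initiation_of_metastatic_specific_therapy": (16, 14),
            "multidrug_to_single_agent": (8, 5),
            "bone_pain": (12, 12),
            "confusion": (0, 1),
            "seizures": (0, 2),
            "fractures": (7, 13),
        },
    },
    TumorType.CRC: {
        "n": 279,
        "n_progressed": 33,
        "anchor": (33, 236),
        "enrollment_months": (30.7, 16.5, 53.4),
        "age_mean_sd": (68.5, 12.5),
        "male_fraction": 0.520,
        "indicators": {
            "secondary_malignancy": (28, 18),
            "different_site_malignancy": (19, 35),
            "radiology_non_primary_site": (32, 175),
            "biopsy_non_primary_site": (19, 29),
            "more_invasive_surgery": (4, 30),
            "surgery_non_primary_site": (7, 8),
            "pain_medication": (21, 113),
            "bone_disease_medication": (0, 2),
            "corticosteroids": (22, 89),
            "ambulatory_aids": (5, 23),
            "radiation_any": (19, 42),
            "initiation_of_radiation": (12, 12),
            "change_in_chemotherapy": (29, 56),
            "initiation_of_metastatic_specific_therapy": (20, 8),
            "bone_pain": (4, 10),
            "confusion": (0, 0),
            "seizures": (0, 0),
            "fractures": (1, 31),
        },
    },
}


@dataclass
class CohortSpec:
    """Parameters of one synthetic tumor-type cohort."""

    tumor_type: TumorType
    n_patients: int
    progression_prevalence: float
    #: indicator name -> (P(positive | progressed), P(positive | not))
    indicator_probs: dict[str, tuple[float, float]]
    #: months: (median, q1, q3) target of the log-normal post-index enrollment
    enrollment_months: tuple[float, float, float]
    #: (P(anchor claim | progressed), P(anchor claim | not))
    anchor_claim_prob: tuple[float, float]
    age_mean_sd: tuple[float, float] = (65.0, 12.0)
    male_fraction: float = 0.5
    #: index dates staggered uniformly over this many days of accrual
    accrual_window_days: int = 2922  # eight calendar years
    #: days from index to progression: uniform over (index+60, enrollment_end]
    progression_time: dict = field(default_factory=lambda: {"kind": "uniform"})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        probs = [self.progression_prevalence, self.male_fraction,
                 *self.anchor_claim_prob]
        for p_pair in self.indicator_probs.values():
            probs.extend(p_pair)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        defined = {d.name for d in indicators_for(self.tumor_type)}
        unknown = set(self.indicator_probs) - defined
        if unknown:
            raise ValueError(
                f"indicators not defined for {self.tumor_type.value}: {sorted(unknown)}"
            )

    def to_dict(self) -> dict:
        return {
            "tumor_type": self.tumor_type.value,
            "n_patients": self.n_patients,
            "progression_prevalence": self.progression_prevalence,
            "indicator_probs": {k: list(v) for k, v in self.indicator_probs.items()},
            "enrollment_months": list(self.enrollment_months),
            "anchor_claim_prob": list(self.anchor_claim_prob),
            "age_mean_sd": list(self.age_mean_sd),
            "male_fraction": self.male_fraction,
            "accrual_window_days": self.accrual_window_days,
            "progression_time": dict(self.progression_time),
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "CohortSpec":
        return CohortSpec(
            tumor_type=TumorType(d["tumor_type"]),
            n_patients=int(d["n_patients"]),
            progression_prevalence=float(d["progression_prevalence"]),
            indicator_probs={k: (float(v[0]), float(v[1]))
                             for k, v in d["indicator_probs"].items()},
            enrollment_months=tuple(d["enrollment_months"]),  # type: ignore[arg-type]
            anchor_claim_prob=tuple(d["anchor_claim_prob"]),  # type: ignore[arg-type]
            age_mean_sd=tuple(d.get("age_mean_sd", (65.0, 12.0))),  # type: ignore[arg-type]
            male_fraction=float(d.get("male_fraction", 0.5)),
            accrual_window_days=int(d.get("accrual_window_days", 2922)),
            progression_time=dict(d.get("progression_time", {"kind": "uniform"})),
            seed=int(d.get("seed", 0)),
        )


def published_profile(tumor_type: TumorType, seed: int = 0) -> CohortSpec:
    """Published conditional-prevalence profile for one tumor type.

    Indicator probabilities are the printed progressed / non-progressed
    prevalences; indicators not reported for a tumor type are absent.
    """
    if not isinstance(tumor_type, TumorType):
        try:
            tumor_type = TumorType(str(tumor_type).upper())
        except ValueError:
            raise ValueError(f"unknown tumor type {tumor_type!r}") from None
    prof = _PROFILE_COUNTS[tumor_type]
    n_prog = prof["n_progressed"]
    n_not = prof["n"] - n_prog
    a_prog, a_not = prof["anchor"]
    return CohortSpec(
        tumor_type=tumor_type,
        n_patients=prof["n"],
        progression_prevalence=n_prog / prof["n"],
        indicator_probs={
            name: (k_prog / n_prog, k_not / n_not)
            for name, (k_prog, k_not) in prof["indicators"].items()
        },
        enrollment_months=prof["enrollment_months"],
        anchor_claim_prob=(a_prog / n_prog, a_not / n_not),
        age_mean_sd=prof["age_mean_sd"],
        male_fraction=prof["male_fraction"],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_Z75 = float(stats.norm.ppf(0.75))


def _lognormal_params(median_m: float, q1_m: float, q3_m: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal (in days) hitting the month targets."""
    mu = float(np.log(median_m * DAYS_PER_MONTH))
    sigma = float(np.log(q3_m / q1_m) / (2.0 * _Z75))
    return mu, sigma


#: Minimum post-index enrollment generated, days.  Eligibility requires 90;
#: the extra headroom guarantees room for an anchor + 30-day lag pattern.
_MIN_FOLLOWUP = 120


class TimelineError(RuntimeError):
    """A patient timeline could not be realised within the retry cap."""


def _draw_followup(rng: np.random.Generator, mu: float, sigma: float) -> int:
    for _ in range(_RETRY_CAP):
        d = int(round(float(rng.lognormal(mu, sigma))))
        if d >= _MIN_FOLLOWUP:
            return d
    raise TimelineError(
        f"could not draw a follow-up >= {_MIN_FOLLOWUP} days in {_RETRY_CAP} tries"
    )


def _coupled_draws(
    rng: np.random.Generator, probs: dict[str, float]
) -> dict[str, bool]:
    """Independent Bernoulli draws with two logical couplings.

    Initiation of radiation implies radiation (any), and a
    multidrug-to-single switch implies a chemotherapy change, so the
    narrower indicator is drawn conditionally inside the wider one; the
    marginals are preserved.
    """
    draws: dict[str, bool] = {}
    nested = {"initiation_of_radiation": "radiation_any",
              "multidrug_to_single_agent": "change_in_chemotherapy"}
    for name, p in probs.items():
        if name in nested:
            continue
        draws[name] = bool(rng.random() < p)
    for narrow, wide in nested.items():
        if narrow not in probs:
            continue
        p_narrow = probs[narrow]
        p_wide = probs.get(wide, 0.0)
        if not draws.get(wide, False) or p_wide <= 0.0:
            draws[narrow] = False
        else:
            draws[narrow] = bool(rng.random() < min(1.0, p_narrow / p_wide))
    return draws


def _anchor_claim(pid: str, day: int, rng: np.random.Generator) -> ClaimEvent:
    # anchors alternate between pathology and primary-site radiology;
    # neither matches any indicator predicate
    if rng.random() < 0.5:
        return ClaimEvent(pid, day, Category.PATHOLOGY)
    return ClaimEvent(pid, day, Category.RADIOLOGY, site=Site.PRIMARY_SITE)


def _pattern_events(
    pid: str,
    ind: IndicatorDef,
    anchor_day: int,
    event_day: int,
    rng: Optional[np.random.Generator] = None,
    multidrug_prior: bool = False,
) -> list[ClaimEvent]:
    """Anchor + qualifying element(s) realising one positive indicator.

    ``anchor_day <= event_day <= anchor_day + 30`` must hold.  For the
    regimen indicators the prior regimen is placed 150 days before the
    new regimen's start (well past the 60-day regimen gap).
    """
    if not (anchor_day <= event_day <= anchor_day + 30):
        raise ValueError("event must fall within 30 days after its anchor")
    events = [ClaimEvent(pid, anchor_day, Category.PATHOLOGY)]
    if ind.mode in (Mode.PRESENCE, Mode.INITIATION, Mode.METASTATIC_SPECIFIC):
        events.append(
            ClaimEvent(pid, event_day, ind.category, site=ind.site or Site.NA)
        )
    elif ind.mode is Mode.MULTI_TO_SINGLE or (
        ind.mode is Mode.CHEMO_CHANGE and multidrug_prior
    ):
        events += [
            ClaimEvent(pid, event_day - 150, Category.CHEMO_AGENT, agent_id="agent_a"),
            ClaimEvent(pid, event_day - 150, Category.CHEMO_AGENT, agent_id="agent_b"),
            ClaimEvent(pid, event_day - 143, Category.CHEMO_AGENT, agent_id="agent_a"),
            ClaimEvent(pid, event_day, Category.CHEMO_AGENT, agent_id="agent_a"),
        ]
    elif ind.mode is Mode.CHEMO_CHANGE:
        events += [
            ClaimEvent(pid, event_day - 150, Category.CHEMO_AGENT, agent_id="agent_a"),
            ClaimEvent(pid, event_day - 143, Category.CHEMO_AGENT, agent_id="agent_a"),
            ClaimEvent(pid, event_day, Category.CHEMO_AGENT, agent_id="agent_b"),
        ]
    else:  # pragma: no cover
        raise AssertionError(f"unhandled mode {ind.mode}")
    return events


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PatientRecord], list[ReferenceOutcome]]:
    """Draw one synthetic cohort realising the spec's marginals.

    Indicators are drawn independently given progression status (the
    published profile gives only marginals); each positive draw is
    realised as an anchor-lag claim pattern, each negative draw leaves
    no qualifying pattern, so the feature engine recovers the draws.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sigma = _lognormal_params(*spec.enrollment_months)
    patients: list[PatientRecord] = []
    outcomes: list[ReferenceOutcome] = []

    for i in range(spec.n_patients):
        pid = f"{spec.tumor_type.value.lower()}-{i:05d}"
        index = 400 + int(rng.integers(0, spec.accrual_window_days))
        start = index - int(rng.integers(180, 366))
        end = index + _draw_followup(rng, mu, sigma)

        progressed = bool(rng.random() < spec.progression_prevalence)
        prog_date: Optional[int] = None
        if progressed:
            prog_date = int(rng.integers(index + 61, end + 1))

        p_anchor = spec.anchor_claim_prob[0] if progressed else spec.anchor_claim_prob[1]
        has_anchor = bool(rng.random() < p_anchor)

        cond = 0 if progressed else 1
        probs = {name: pair[cond] for name, pair in spec.indicator_probs.items()}
        draws = _coupled_draws(rng, probs)
        if not has_anchor:
            # no anchor claim => no indicator can fire; force draws negative
            # (anchor prevalence is near-total in every published cohort,
            # so the distortion of the conditional prevalences is tiny)
            any_pos = any(draws.values())
            if any_pos:
                has_anchor = True

        events: list[ClaimEvent] = [
            # diagnostic work-up around the index date (never anchors)
            ClaimEvent(pid, index, Category.RADIOLOGY, site=Site.PRIMARY_SITE),
            ClaimEvent(pid, min(index + 5, end), Category.PATHOLOGY),
        ]

        if has_anchor:
            n_filler = 1 + int(rng.integers(0, 3))
            for _ in range(n_filler):
                events.append(_anchor_claim(pid, int(rng.integers(index + 60, end + 1)), rng))

        for name, positive in draws.items():
            if not positive:
                continue
            ind = indicator(name)
            anchor_day, event_day = _place_window(
                rng, index, end, prog_date if (progressed and name == "secondary_malignancy") else None
            )
            if name == "radiation_any" and not draws.get("initiation_of_radiation", False):
                # a pre-index course blocks the initiation variant
                events.append(ClaimEvent(pid, max(start, index - 30), Category.RADIATION))
            if name == "initiation_of_radiation":
                continue  # realised by the radiation_any pattern (no prior course)
            if name == "change_in_chemotherapy":
                events += _pattern_events(
                    pid, ind, anchor_day, event_day,
                    multidrug_prior=draws.get("multidrug_to_single_agent", False),
                )
                continue
            if name == "multidrug_to_single_agent":
                continue  # realised inside the chemotherapy-change pattern
            events += _pattern_events(pid, ind, anchor_day, event_day)

        age = float(np.clip(rng.normal(*spec.age_mean_sd), 18.0, 95.0))
        sex = Sex.M if rng.random() < spec.male_fraction else Sex.F
        if spec.tumor_type is TumorType.BREAST:
            sex = Sex.F
        stage = Stage(("I", "II", "III")[int(rng.integers(0, 3))])

        patients.append(
            PatientRecord(
                patient_id=pid,
                tumor_type=spec.tumor_type,
                age_at_index=round(age, 1),
                sex=sex,
                stage_at_dx=stage,
                index_date=index,
                enrollment_start=start,
                enrollment_end=end,
                events=events,
            )
        )
        outcomes.append(ReferenceOutcome(pid, progressed, prog_date))
    return patients, outcomes


def _place_window(
    rng: np.random.Generator,
    index: int,
    end: int,
    near_progression: Optional[int],
) -> tuple[int, int]:
    """Pick (anchor day, element day) for one positive indicator.

    Generic placement is uniform over the feasible post-washout range;
    when ``near_progression`` is given (the secondary-malignancy claim
    of a progressed patient) the element lands within +/-20 days of the
    progression date so that timing-matched evaluation can succeed.
    """
    if near_progression is not None:
        event_day = int(np.clip(near_progression + int(rng.integers(-20, 21)),
                                index + 61, end))
        anchor_day = max(index + 60, event_day - int(rng.integers(0, 16)))
        return anchor_day, event_day
    anchor_day = int(rng.integers(index + 61, max(index + 62, end - 30)))
    event_day = min(end, anchor_day + int(rng.integers(0, 31)))
    return anchor_day, event_day


# ---------------------------------------------------------------------------
# Deterministic confusion-matrix fixtures
# ---------------------------------------------------------------------------


def generate_fixture_confusion(
    tumor_type: TumorType,
    algorithm: AlgorithmSpec,
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    seed: int = 0,
) -> tuple[list[PatientRecord], list[ReferenceOutcome]]:
    """Cohort that realises exactly the requested 2x2 cells end-to-end.

    True positives are progressed patients whose triggering claims sit
    within +/-90 days of the progression date; false negatives are
    progressed with no qualifying pattern; false positives carry the
    pattern without progression; true negatives carry neither.  With
    the default feature windows and the +/-90-day match, the full
    pipeline reproduces ConfusionMatrix(tp, fp, fn, tn).
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("cell counts must be non-negative")
    if tp + fn < 1 and fp + tn < 1:
        raise ValueError("at least one class must be non-empty")
    defined = {d.name for d in indicators_for(tumor_type)}
    missing = algorithm.rule.leaves() - defined
    if missing:
        raise ValueError(
            f"algorithm {algorithm.name!r} references indicators undefined for "
            f"{tumor_type.value}: {sorted(missing)}"
        )

    rng = np.random.default_rng(seed)
    patients: list[PatientRecord] = []
    outcomes: list[ReferenceOutcome] = []
    counter = 0

    def build(kind: str, progressed: bool, with_pattern: bool) -> None:
        nonlocal counter
        pid = f"{tumor_type.value.lower()}-{kind}-{counter:05d}"
        counter += 1
        index = 400 + int(rng.integers(0, 200))
        start, end = index - 200, index + 500
        prog_date = index + 250 if progressed else None
        events = [ClaimEvent(pid, index, Category.RADIOLOGY, site=Site.PRIMARY_SITE)]
        if with_pattern:
            day = (prog_date + 10) if progressed else index + 260
            anchor_day = day - 10
            leaves = sorted(algorithm.rule.leaves())
            both_chemo = ("change_in_chemotherapy" in leaves
                          and "multidrug_to_single_agent" in leaves)
            for name in leaves:
                if both_chemo and name == "multidrug_to_single_agent":
                    continue  # realised by the chemotherapy-change pattern below
                events += _pattern_events(
                    pid, indicator(name), anchor_day, day,
                    multidrug_prior=(both_chemo and name == "change_in_chemotherapy"),
                )
        else:
            events.append(ClaimEvent(pid, index + 100, Category.PATHOLOGY))
        patients.append(
            PatientRecord(
                patient_id=pid,
                tumor_type=tumor_type,
                age_at_index=60.0,
                sex=Sex.F if tumor_type is TumorType.BREAST else Sex.M,
                stage_at_dx=Stage.II,
                index_date=index,
                enrollment_start=start,
                enrollment_end=end,
                events=events,
            )
        )
        outcomes.append(ReferenceOutcome(pid, progressed, prog_date))

    for _ in range(tp):
        build("tp", progressed=True, with_pattern=True)
    for _ in range(fn):
        build("fn", progressed=True, with_pattern=False)
    for _ in range(fp):
        build("fp", progressed=False, with_pattern=True)
    for _ in range(tn):
        build("tn", progressed=False, with_pattern=False)
    return patients, outcomes
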