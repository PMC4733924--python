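"""Anchor-lag indicator construction, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from metaclaims.feature_engine import (
    ANCHOR_INDICATOR,
    FeatureConfig,
    Mode,
    anchor_dates,
    apply_delayed_window_exclusion,
    chemo_change_triggered,
    element_triggered,
    extract_features,
    feature_matrix,
    indicator,
    indicators_for,
    initiation_triggered,
    with_window,
)
from metaclaims.types import Category, ClaimEvent, ReferenceOutcome, Site, TumorType

from conftest import ev, make_patient, random_event_stream

CFG = FeatureConfig()


# ---------------------------------------------------------------------------
# Independent oracles: exhaustive scans, no shared code with the engine
# ---------------------------------------------------------------------------


def oracle_anchors(patient, config):
    out = []
    for e in patient.events:
        if e.category in (Category.RADIOLOGY, Category.PATHOLOGY):
            if e.date - patient.index_date >= config.anchor_min_days_after_index:
                out.append(e.date)
    return sorted(out)


def oracle_presence(patient, ind, config):
    anchors = oracle_anchors(patient, config)
    hits = []
    for a in anchors:
        for e in patient.events:
            if ind.matches(e) and a <= e.date <= a + config.element_lag:
                hits.append(e.date)
    return (True, min(hits)) if hits else (False, None)


def oracle_initiation(patient, ind, config):
    hit, day = oracle_presence(patient, ind, config)
    if not hit:
        return False, None
    prior = [e for e in patient.events if e.category is ind.category and e.date < day]
    return (False, None) if prior else (True, day)


class TestAnchorDates:
    def test_sixty_day_boundary_inclusive(self):
        p = make_patient([
            ev("p0", 459, Category.RADIOLOGY, Site.PRIMARY_SITE),  # index+59
            ev("p0", 460, Category.RADIOLOGY, Site.PRIMARY_SITE),  # index+60
        ])
        assert anchor_dates(p, CFG) == [460]

    def test_no_radiology_pathology_gives_empty(self):
        p = make_patient([ev("p0", 500, Category.OPIOID)])
        assert anchor_dates(p, CFG) == []

    def test_duplicates_retained_and_sorted(self):
        p = make_patient([
            ev("p0", 700, Category.PATHOLOGY),
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 500, Category.RADIOLOGY, Site.OTHER_SITE),
        ])
        assert anchor_dates(p, CFG) == [500, 500, 700]

    def test_matches_brute_force_on_random_streams(self, rng):
        for i in range(5):
            events = random_event_stream(rng, "p0", 400, 2000, 15)
            p = make_patient(events)
            assert anchor_dates(p, CFG) == oracle_anchors(p, CFG)


class TestElementWindows:
    def test_thirty_day_boundary_inclusive(self):
        p = make_patient([
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 530, Category.OPIOID),
        ])
        opioid = indicator("pain_medication")
        assert element_triggered(p, opioid, [500], CFG) == (True, 530)

    def test_day_thirty_one_misses(self):
        p = make_patient([
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 531, Category.OPIOID),
        ])
        opioid = indicator("pain_medication")
        assert element_triggered(p, opioid, [500], CFG) == (False, None)

    def test_element_may_pair_with_any_anchor(self):
        p = make_patient([
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 600, Category.PATHOLOGY),
            ev("p0", 620, Category.OPIOID),
        ])
        opioid = indicator("pain_medication")
        assert element_triggered(p, opioid, [500, 600], CFG) == (True, 620)

    def test_wrong_tumor_type_rejected(self):
        p = make_patient(tumor_type=TumorType.CRC)
        with pytest.raises(ValueError):
            element_triggered(p, indicator("lump_swelling"), [], CFG)


class TestInitiation:
    def test_prior_course_blocks_initiation_but_not_presence(self):
        p = make_patient([
            ev("p0", 420, Category.RADIATION),  # pre-anchor course
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 530, Category.RADIATION),
        ])
        anchors = anchor_dates(p, CFG)
        any_rad = indicator("radiation_any")
        init_rad = indicator("initiation_of_radiation")
        assert element_triggered(p, any_rad, anchors, CFG) == (True, 530)
        assert initiation_triggered(p, init_rad, anchors, CFG) == (False, None)

    def test_naive_start_triggers(self):
        p = make_patient([
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 530, Category.RADIATION),
        ])
        anchors = anchor_dates(p, CFG)
        assert initiation_triggered(p, indicator("initiation_of_radiation"), anchors, CFG) \
            == (True, 530)


class TestChemoChange:
    def _patient_with_regimens(self, prior_agents, new_agents, new_start=700):
        events = [ev("p0", 690, Category.PATHOLOGY)]  # anchor; window [690, 720]
        for a in sorted(prior_agents):
            events.append(ev("p0", new_start - 200, Category.CHEMO_AGENT, agent=a))
        for a in sorted(new_agents):
            events.append(ev("p0", new_start, Category.CHEMO_AGENT, agent=a))
        return make_patient(events)

    def test_agent_set_change_triggers(self):
        p = self._patient_with_regimens({"A", "B"}, {"A", "C"})
        anchors = anchor_dates(p, CFG)
        assert chemo_change_triggered(p, anchors, CFG) == (True, 700)

    def test_single_continuous_regimen_never_triggers(self):
        events = [ev("p0", 690, Category.PATHOLOGY)] + [
            ev("p0", d, Category.CHEMO_AGENT, agent="A") for d in range(500, 800, 30)
        ]
        p = make_patient(events)
        assert chemo_change_triggered(p, anchor_dates(p, CFG), CFG) == (False, None)

    def test_regimen_start_outside_anchor_window_ignored(self):
        p = self._patient_with_regimens({"A"}, {"B"}, new_start=750)  # window ends 720
        assert chemo_change_triggered(p, anchor_dates(p, CFG), CFG) == (False, None)

    def test_all_two_regimen_agent_set_pairs_against_truth_table(self):
        """Exhaustive enumeration over agent subsets of {A,B,C}."""
        agents = ["A", "B", "C"]
        subsets = [set(c) for r in (1, 2, 3) for c in itertools.combinations(agents, r)]
        for prior, new in itertools.product(subsets, subsets):
            p = self._patient_with_regimens(prior, new)
            anchors = anchor_dates(p, CFG)
            want_change = prior != new
            want_m2s = prior != new and len(prior) >= 2 and len(new) == 1
            got_change, d1 = chemo_change_triggered(p, anchors, CFG)
            got_m2s, d2 = chemo_change_triggered(p, anchors, CFG, multidrug_to_single=True)
            assert got_change is want_change, (prior, new)
            assert got_m2s is want_m2s, (prior, new)
            if want_change:
                assert d1 == 700

    def test_agent_set_limited_to_regimen_window(self):
        # agent C joins 100 days into the new regimen: outside the 90-day
        # agent-set window, so the set stays {A} and matches the prior one
        events = [
            ev("p0", 690, Category.PATHOLOGY),
            ev("p0", 450, Category.CHEMO_AGENT, agent="A"),
            ev("p0", 700, Category.CHEMO_AGENT, agent="A"),
            ev("p0", 750, Category.CHEMO_AGENT, agent="A"),
            ev("p0", 800, Category.CHEMO_AGENT, agent="C"),
        ]
        p = make_patient(events)
        assert chemo_change_triggered(p, anchor_dates(p, CFG), CFG) == (False, None)


class TestExtractFeatures:
    def test_no_anchor_means_all_false(self, rng):
        events = [e for e in random_event_stream(rng, "p0", 400, 2000, 12)
                  if e.category not in (Category.RADIOLOGY, Category.PATHOLOGY)
                  or e.date < 460]
        p = make_patient(events)
        fv = extract_features(p, CFG)
        assert not fv.indicators[ANCHOR_INDICATOR]
        assert not any(fv.indicators.values())

    def test_single_planted_indicator(self):
        p = make_patient([
            ev("p0", 500, Category.PATHOLOGY),
            ev("p0", 510, Category.SECONDARY_MALIGNANCY_DX),
        ])
        fv = extract_features(p, CFG)
        positives = {k for k, v in fv.indicators.items() if v}
        assert positives == {ANCHOR_INDICATOR, "secondary_malignancy"}
        assert fv.first_trigger["secondary_malignancy"] == 510

    def test_oracle_equivalence_on_random_streams(self, rng):
        """Every PRESENCE/INITIATION indicator equals the exhaustive scan."""
        for i in range(200):
            tt = (TumorType.BREAST, TumorType.NSCLC, TumorType.CRC)[i % 3]
            n_events = int(rng.integers(0, 21))
            events = random_event_stream(rng, "p0", 400, 2000, n_events)
            p = make_patient(events, tumor_type=tt)
            fv = extract_features(p, CFG)
            for ind in indicators_for(tt):
                if ind.mode is Mode.PRESENCE:
                    want = oracle_presence(p, ind, CFG)
                elif ind.mode in (Mode.INITIATION, Mode.METASTATIC_SPECIFIC):
                    want = oracle_initiation(p, ind, CFG)
                else:
                    continue
                assert (fv.indicators[ind.name], fv.first_trigger[ind.name]) == want, ind.name

    def test_window_monotonicity(self, rng):
        """A later anchor cutoff never adds anchors or flips false->true."""
        for _ in range(30):
            events = random_event_stream(rng, "p0", 400, 2000, 15)
            p = make_patient(events)
            prev = extract_features(p, FeatureConfig())
            for w in (90, 120, 180, 365):
                cur = extract_features(p, with_window(CFG, w))
                assert set(cur.anchor_dates) <= set(prev.anchor_dates)
                for name, val in cur.indicators.items():
                    if val:
                        assert prev.indicators[name], (name, w)
                prev = cur

    def test_shift_equivariance(self, rng):
        for _ in range(20):
            events = random_event_stream(rng, "p0", 400, 2000, 12)
            p = make_patient(events)
            shift = 137
            shifted = make_patient(
                [ClaimEvent("p0", e.date + shift, e.category, site=e.site,
                            agent_id=e.agent_id) for e in events],
                index_date=400 + shift,
                enrollment_start=100 + shift,
                enrollment_end=2000 + shift,
            )
            a = extract_features(p, CFG)
            b = extract_features(shifted, CFG)
            assert a.indicators == b.indicators
            for name, day in a.first_trigger.items():
                want = None if day is None else day + shift
                assert b.first_trigger[name] == want


class TestFeatureMatrix:
    def test_counts_match_hand_placement(self):
        p1 = make_patient([
            ev("a", 500, Category.PATHOLOGY),
            ev("a", 510, Category.SECONDARY_MALIGNANCY_DX),
        ], patient_id="a")
        p2 = make_patient([], patient_id="b")
        outs = [ReferenceOutcome("a", True, 505), ReferenceOutcome("b", False, None)]
        fm = feature_matrix([p1, p2], outs, CFG)
        assert fm.loc["secondary_malignancy", "n_progressed"] == 1
        assert fm.loc["secondary_malignancy", "n_not_progressed"] == 0
        assert fm.loc[ANCHOR_INDICATOR, "pct_progressed"] == 100.0

    def test_breast_report_has_26_rows(self):
        p = make_patient([])
        out = [ReferenceOutcome("p0", False, None)]
        fm = feature_matrix([p], out, CFG)
        assert len(fm) == 26  # 25 indicators + the anchor pseudo-indicator

    def test_empty_stratum_reports_zero(self):
        p = make_patient([])
        fm = feature_matrix([p], [ReferenceOutcome("p0", False, None)], CFG)
        assert fm.attrs["n_progressed"] == 0
        assert (fm["pct_progressed"] == 0).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            feature_matrix([], [], CFG)


class TestDelayedWindowExclusion:
    def test_short_followup_dropped_only_for_delayed_windows(self):
        p_short = make_patient([], patient_id="s", enrollment_end=700)  # 300 d of follow-up
        p_long = make_patient([], patient_id="l")
        outs = [ReferenceOutcome("s", False, None), ReferenceOutcome("l", False, None)]
        kept, _ = apply_delayed_window_exclusion([p_short, p_long], outs, CFG)
        assert len(kept) == 2
        kept90, _ = apply_delayed_window_exclusion(
            [p_short, p_long], outs, with_window(CFG, 90)
        )
        assert [p.patient_id for p in kept90] == ["l"]

    def test_early_progression_dropped_for_delayed_windows(self):
        p = make_patient([], patient_id="e")
        outs = [ReferenceOutcome("e", True, 700)]  # progressed day 300 post-index
        kept, _ = apply_delayed_window_exclusion([p], outs, with_window(CFG, 120))
        assert kept == []
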