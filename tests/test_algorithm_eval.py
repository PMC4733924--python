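"""Candidate models, timing-matched classification, 2x2 measures."""

import numpy as np
import pytest

from metaclaims.algorithm_eval import (
    Cell,
    MatchConfig,
    apply_algorithm,
    builtin_algorithms,
    classify,
    evaluate,
    evaluation_report,
    reconstruct_confusion,
)
from metaclaims.feature_engine import FeatureVector, indicators_for
from metaclaims.types import (
    ConfusionMatrix,
    PerformanceMeasures,
    ReferenceOutcome,
    TumorType,
)


def fv(pid="p0", **triggers):
    """Feature vector from name -> first-trigger day (None = negative)."""
    names = {d.name for tt in TumorType for d in indicators_for(tt)}
    names.add("radiology_pathology_claim")
    indicators = {n: triggers.get(n) is not None for n in names}
    first = {n: triggers.get(n) for n in names}
    return FeatureVector(pid, anchor_dates=[], indicators=indicators, first_trigger=first)


class TestBuiltinAlgorithms:
    def test_model_counts_per_tumor_type(self):
        assert len(builtin_algorithms(TumorType.BREAST)) == 3
        assert len(builtin_algorithms(TumorType.NSCLC)) == 3
        assert len(builtin_algorithms(TumorType.CRC)) == 2

    def test_every_leaf_is_a_defined_indicator(self):
        for tt in TumorType:
            defined = {d.name for d in indicators_for(tt)}
            for spec in builtin_algorithms(tt):
                assert spec.rule.leaves() <= defined, spec.name

    def test_nsclc_model3_fires_on_diff_site_plus_chemo_change(self):
        m3 = builtin_algorithms(TumorType.NSCLC)[2]
        vec = fv(different_site_malignancy=300, change_in_chemotherapy=320)
        positive, day = apply_algorithm(m3, vec)
        assert positive and day == 320  # AND of the two triggers

    def test_crc_model2_is_secondary_or_chemo_change(self):
        m2 = builtin_algorithms(TumorType.CRC)[1]
        assert m2.rule.leaves() == {"secondary_malignancy", "change_in_chemotherapy"}
        assert apply_algorithm(m2, fv(change_in_chemotherapy=500))[0]


class TestApplyAlgorithm:
    def test_single_leaf_detection_date(self):
        m1 = builtin_algorithms(TumorType.BREAST)[0]
        assert apply_algorithm(m1, fv(secondary_malignancy=200)) == (True, 200)

    def test_breast_m3_and_is_max_of_satisfied_children(self):
        m3 = builtin_algorithms(TumorType.BREAST)[2]
        vec = fv(secondary_malignancy=150, initiation_of_immunotherapy=220)
        positive, day = apply_algorithm(m3, vec)
        assert positive and day == 220

    def test_breast_m3_day_by_day_brute_force(self):
        """Detection date equals the first day the rule holds when each
        indicator 'switches on' at its trigger date."""
        m3 = builtin_algorithms(TumorType.BREAST)[2]
        triggers = {"secondary_malignancy": 150,
                    "different_site_malignancy": 400,
                    "initiation_of_immunotherapy": 220}
        vec = fv(**triggers)
        _, day = apply_algorithm(m3, vec)
        first = next(
            d for d in range(0, 500)
            if m3.rule.evaluate({n: (t is not None and t <= d)
                                 for n, t in vec.first_trigger.items()})
        )
        assert day == first == 220

    def test_all_false_vector_negative(self):
        m1 = builtin_algorithms(TumorType.BREAST)[0]
        assert apply_algorithm(m1, fv()) == (False, None)

    def test_missing_leaf_rejected(self):
        m1 = builtin_algorithms(TumorType.BREAST)[0]
        bad = FeatureVector("p0", [], {"pain_medication": True}, {"pain_medication": 1})
        with pytest.raises(ValueError):
            apply_algorithm(m1, bad)


class TestClassify:
    def test_match_window_boundary_inclusive(self):
        out = ReferenceOutcome("p0", True, 300)
        assert classify(True, 390, out) is Cell.TP  # exactly +90
        assert classify(True, 391, out) is Cell.FN
        assert classify(True, 210, out) is Cell.TP  # exactly -90
        assert classify(True, 209, out) is Cell.FN

    def test_non_progressed_positive_is_fp_any_time(self):
        out = ReferenceOutcome("p0", False, None)
        assert classify(True, 50, out) is Cell.FP
        assert classify(False, None, out) is Cell.TN

    def test_progressed_negative_is_fn(self):
        assert classify(False, None, ReferenceOutcome("p0", True, 300)) is Cell.FN

    def test_mistimed_positive_configurable_to_fp(self):
        out = ReferenceOutcome("p0", True, 300)
        cfg = MatchConfig(mistimed_as_fp=True)
        assert classify(True, 500, out, cfg) is Cell.FP

    def test_positive_without_date_rejected(self):
        with pytest.raises(ValueError):
            classify(True, None, ReferenceOutcome("p0", False, None))


class TestEvaluate:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((11, 68, 6, 417), (64.7, 86.0, 13.9, 98.6)),
            ((37, 41, 24, 134), (60.7, 76.6, 47.4, 84.8)),
            ((14, 18, 19, 228), (42.4, 92.7, 43.8, 92.3)),
        ],
        ids=["breast_m1", "nsclc_m1", "crc_m1"],
    )
    def test_published_measures_from_cells(self, cells, expected):
        pm = PerformanceMeasures.from_confusion(ConfusionMatrix(*cells))
        assert (pm.sensitivity, pm.specificity, pm.ppv, pm.npv) == expected

    def test_aggregation_matches_per_patient_classification(self):
        m1 = builtin_algorithms(TumorType.BREAST)[0]
        fvs = [
            fv("tp", secondary_malignancy=310),
            fv("fn1"),
            fv("fn2", secondary_malignancy=800),  # mistimed
            fv("fp", secondary_malignancy=100),
            fv("tn"),
        ]
        outs = [
            ReferenceOutcome("tp", True, 300),
            ReferenceOutcome("fn1", True, 300),
            ReferenceOutcome("fn2", True, 300),
            ReferenceOutcome("fp", False, None),
            ReferenceOutcome("tn", False, None),
        ]
        cm, _ = evaluate(fvs, outs, m1)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 2, 1)

    def test_report_contains_all_models(self):
        m = builtin_algorithms(TumorType.CRC)
        fvs = [fv("a", secondary_malignancy=310), fv("b")]
        outs = [ReferenceOutcome("a", True, 300), ReferenceOutcome("b", False, None)]
        report = evaluation_report(fvs, outs, m)
        assert len(report) == 2
        assert report.loc[("CRC", "model_1"), "sensitivity"] == 100.0


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "args,cells",
        [
            ((17, 485, 64.7, 86.0), (11, 68, 6, 417)),
            ((61, 175, 60.7, 76.6), (37, 41, 24, 134)),
            ((33, 246, 42.4, 92.7), (14, 18, 19, 228)),
            ((10, 10, 100.0, 100.0), (10, 0, 0, 10)),
        ],
    )
    def test_reconstructs_unique_cell_solution(self, args, cells):
        cm = reconstruct_confusion(*args)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == cells

    def test_brute_force_uniqueness_for_breast(self):
        """Only one integer table with these marginals rounds to the
        printed one-decimal rates."""
        matches = [
            (tp, 485 - tn)
            for tp in range(18)
            for tn in range(486)
            if round(100 * tp / 17, 1) == 64.7 and round(100 * tn / 485, 1) == 86.0
        ]
        assert matches == [(11, 68)]

    def test_right_inverse_of_rate_computation(self, rng):
        for _ in range(1000):
            tp, fp, fn, tn = (int(rng.integers(0, 60)) for _ in range(4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            pm = PerformanceMeasures.from_confusion(ConfusionMatrix(tp, fp, fn, tn))
            back = reconstruct_confusion(tp + fn, tn + fp, pm.sensitivity, pm.specificity)
            assert (back.tp, back.fp, back.fn, back.tn) == (tp, fp, fn, tn)

    def test_sensitivity_specificity_complements(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = (int(rng.integers(0, 40)) for _ in range(4))
            cm = ConfusionMatrix(tp, fp, fn, tn)
            if tp + fn:
                miss = 100.0 * fn / (tp + fn)
                assert 100.0 * tp / (tp + fn) + miss == pytest.approx(100.0)
            if tn + fp:
                fpr = 100.0 * fp / (tn + fp)
                assert 100.0 * tn / (tn + fp) + fpr == pytest.approx(100.0)

    def test_ppv_nondecreasing_in_prevalence(self):
        sens, spec = 64.7, 86.0
        last = -1.0
        for n_pos in range(5, 100, 5):
            n_neg = 200 - n_pos
            tp = sens / 100 * n_pos
            fp = (1 - spec / 100) * n_neg
            ppv = 100 * tp / (tp + fp)
            assert ppv >= last
            last = ppv

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(10, 10, 120.0, 50.0)
        with pytest.raises(ValueError):
            reconstruct_confusion(-1, 10, 50.0, 50.0)
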