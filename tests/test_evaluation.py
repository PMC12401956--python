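"""Tests for the CV harness, metric formulas, ROC/AUC, and the experiment."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bloodml import evaluation as ev
from bloodml import gwo_select as gw
from bloodml import synthetic_cohort as sc

from conftest import make_specs

FAST_GWO = gw.GWOParams(pop_size=4, n_iter=3, seed=0)
FAST_FITNESS = gw.FitnessSpec(classifier_id="knn", cv_folds=3, seed=0)


class TestFoldPlan:
    def test_k10_x5_gives_50_test_sets(self):
        y = np.r_[np.zeros(60, dtype=int), np.ones(60, dtype=int)]
        plan = ev.make_fold_plan(y, k=10, repeats=5, seed=0)
        test_sets = {
            tuple(plan.test_indices(r, f)) for r in range(5) for f in range(10)
        }
        assert len(test_sets) == 50

    def test_folds_partition_subjects(self):
        y = np.r_[np.zeros(33, dtype=int), np.ones(29, dtype=int)]
        plan = ev.make_fold_plan(y, k=5, repeats=3, seed=1)
        for r in range(3):
            seen = np.concatenate([plan.test_indices(r, f) for f in range(5)])
            assert sorted(seen) == list(range(62))

    def test_stratification_within_one(self):
        # 51/49 class mix: every fold's case count within +/-1 of n_case/k
        y = np.r_[np.ones(51, dtype=int), np.zeros(49, dtype=int)]
        plan = ev.make_fold_plan(y, k=10, repeats=4, seed=2)
        for r in range(4):
            for f in range(10):
                n_case = y[plan.test_indices(r, f)].sum()
                assert abs(n_case - 5.1) <= 1

    def test_class_smaller_than_k_is_error(self):
        y = np.r_[np.zeros(30, dtype=int), np.ones(5, dtype=int)]
        with pytest.raises(ValueError, match="fewer than k"):
            ev.make_fold_plan(y, k=10, repeats=1, seed=0)

    def test_deterministic(self):
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        a = ev.make_fold_plan(y, k=4, repeats=2, seed=3)
        b = ev.make_fold_plan(y, k=4, repeats=2, seed=3)
        for fa, fb in zip(a.assignments, b.assignments):
            np.testing.assert_array_equal(fa, fb)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        c = ev.confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (2, 2)

    def test_all_positive_prediction(self):
        c = ev.confusion_counts([1, 0, 0, 0], [1, 1, 1, 1])
        assert c.tn == 0
        assert c.fp == 3

    def test_hand_enumeration(self):
        c = ev.confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.confusion_counts([1, 0], [1])

    def test_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            ev.confusion_counts([1, 2], [1, 0])


def metric_oracle(tp, tn, fp, fn):
    """Independent exact-arithmetic oracle for the metric formulas."""
    def ratio(num, den):
        return Fraction(num, den) if den else Fraction(0)

    acc = Fraction(tp + tn, tp + tn + fp + fn)
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else Fraction(0)
    return acc, sens, spec, prec, f1


class TestComputeMetrics:
    def test_worked_example(self):
        ms = ev.compute_metrics(ev.ConfusionCounts(tp=96, tn=95, fp=5, fn=4))
        assert ms.accuracy == pytest.approx(0.955, abs=1e-12)
        assert ms.sensitivity == pytest.approx(0.96, abs=1e-12)
        assert ms.specificity == pytest.approx(0.95, abs=1e-12)
        assert ms.precision == pytest.approx(96 / 101, abs=1e-12)
        expected_f1 = float(metric_oracle(96, 95, 5, 4)[4])
        assert ms.f1 == pytest.approx(expected_f1, abs=1e-12)

    def test_perfect_counts_all_one(self):
        ms = ev.compute_metrics(ev.ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (ms.accuracy, ms.sensitivity, ms.specificity, ms.precision, ms.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )
        assert not ms.undefined

    def test_undefined_precision_flagged(self):
        ms = ev.compute_metrics(ev.ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert ms.precision == 0.0
        assert "precision" in ms.undefined

    def test_empty_counts_error(self):
        with pytest.raises(ValueError, match="empty"):
            ev.compute_metrics(ev.ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    @given(
        tp=st.integers(0, 500), tn=st.integers(0, 500),
        fp=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_arithmetic_oracle(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        ms = ev.compute_metrics(ev.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        acc, sens, spec, prec, f1 = metric_oracle(tp, tn, fp, fn)
        assert ms.accuracy == pytest.approx(float(acc), abs=1e-12)
        assert ms.sensitivity == pytest.approx(float(sens), abs=1e-12)
        assert ms.specificity == pytest.approx(float(spec), abs=1e-12)
        assert ms.precision == pytest.approx(float(prec), abs=1e-12)
        assert ms.f1 == pytest.approx(float(f1), abs=1e-12)

    def test_f1_consistency_with_reported_precision_recall(self):
        ms = ev.compute_metrics(ev.ConfusionCounts(tp=37, tn=22, fp=13, fn=9))
        expected = 2 * ms.precision * ms.sensitivity / (ms.precision + ms.sensitivity)
        assert ms.f1 == pytest.approx(expected, abs=1e-9)


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = ev.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_equal_scores_gives_half(self):
        _, auc = ev.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_reversed_ranking_gives_zero(self):
        _, auc = ev.roc_auc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert auc == 0.0

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1, 1], [0.3, 0.4])

    def test_curve_starts_and_ends_at_corners(self):
        curve, _ = ev.roc_auc([0, 1, 1, 0], [0.2, 0.9, 0.4, 0.5])
        assert curve[0].tolist() == [0.0, 0.0]
        assert curve[-1].tolist() == [1.0, 1.0]

    def test_random_scores_near_half(self, rng):
        n = 1000
        y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
        scores = rng.random(2 * n)
        _, auc = ev.roc_auc(y, scores)
        se = np.sqrt((2 * n + 1) / (12.0 * n * n))  # Mann-Whitney null SE
        assert abs(auc - 0.5) < 3 * se

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_normalized_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = 37, 43
        y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
        # coarse grid forces plenty of ties
        scores = rng.integers(0, 10, size=n_pos + n_neg).astype(float)
        _, auc = ev.roc_auc(y, scores)
        u = sps.mannwhitneyu(scores[:n_pos], scores[n_pos:]).statistic
        assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-10)


@pytest.fixture(scope="module")
def small_report():
    specs = make_specs(5, shift=2.5, n_informative=2)
    cohort = sc.generate_cohort(
        sc.CohortConfig(n_control=40, n_case=40, seed=17), specs
    )
    config = ev.ExperimentConfig(
        k=4, repeats=2, seed=1, gwo_params=FAST_GWO, fitness=FAST_FITNESS,
    )
    return ev.run_experiment(cohort, config)


class TestRunExperiment:
    def test_report_shape_contract(self, small_report):
        # 5 models x 2 conditions x 5 metrics (+ AUC), none missing
        assert set(small_report.metrics) == {
            (m, c) for m in ev.classifiers.MODEL_IDS for c in ev.CONDITIONS
        }
        for ms in small_report.metrics.values():
            for value in ms.as_dict().values():
                assert value is not None and 0.0 <= value <= 1.0
        assert set(small_report.pooled_auc) == set(small_report.metrics)
        assert set(small_report.roc_curves) == set(small_report.metrics)

    def test_selected_features_non_empty(self, small_report):
        assert len(small_report.selected_features) >= 1
        assert small_report.convergence_trace

    def test_importances_for_tree_models_only(self, small_report):
        assert set(small_report.importances) == {"random_forest", "gradient_boosting"}
        for imps in small_report.importances.values():
            assert abs(sum(imps.values()) - 1.0) < 1e-9

    def test_signal_recovery_tree_models(self):
        # planted strongly-separable cohort: tree models should be near-perfect
        specs = make_specs(4, shift=6.0)
        cohort = sc.generate_cohort(
            sc.CohortConfig(n_control=40, n_case=40, seed=23), specs
        )
        config = ev.ExperimentConfig(
            k=4, repeats=1, seed=0,
            models=("random_forest", "gradient_boosting"),
            gwo_params=FAST_GWO, fitness=FAST_FITNESS,
        )
        report = ev.run_experiment(cohort, config)
        for model in config.models:
            assert report.metrics[(model, "before_gwo")].accuracy > 0.9

    def test_null_cohort_accuracy_near_majority_share(self, null_cohort):
        config = ev.ExperimentConfig(
            k=4, repeats=1, seed=2, models=("logistic_regression",),
            gwo_params=FAST_GWO, fitness=FAST_FITNESS,
        )
        report = ev.run_experiment(null_cohort, config)
        acc = report.metrics[("logistic_regression", "before_gwo")].accuracy
        assert abs(acc - 0.5) < 0.15

    def test_determinism(self, null_cohort):
        config = ev.ExperimentConfig(
            k=3, repeats=1, seed=4, models=("knn",),
            gwo_params=FAST_GWO, fitness=FAST_FITNESS,
        )
        a = ev.run_experiment(null_cohort, config).metrics_frame()
        b = ev.run_experiment(null_cohort, config).metrics_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_metrics_frame_columns(self, small_report):
        frame = small_report.metrics_frame()
        assert {"model", "condition", "accuracy", "sensitivity", "specificity",
                "precision", "f1", "auc", "pooled_auc"} <= set(frame.columns)
        assert len(frame) == 10
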