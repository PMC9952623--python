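"""SVM cross-validation and the confusion-matrix metric suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgkit import (
    ClassifierConfig,
    ConfusionMatrix,
    ContractError,
    MetricsReport,
    aggregate_metrics,
    compute_metrics,
    cross_validate,
    g_mean,
)


class TestComputeMetrics:
    def test_best_case_normal_positive(self):
        m = compute_metrics(ConfusionMatrix(tp=29, fn=1, fp=3, tn=17))
        assert m["sensitivity"] == pytest.approx(96.7, abs=0.05)
        assert m["specificity"] == pytest.approx(85.0, abs=0.05)
        assert m["precision"] == pytest.approx(90.6, abs=0.05)
        assert m["f_beta"] == pytest.approx(0.935, abs=0.001)
        assert m["accuracy"] == pytest.approx(92.0, abs=0.05)

    def test_best_case_suspicious_positive(self):
        m = compute_metrics(ConfusionMatrix(tp=17, fn=3, fp=1, tn=29))
        assert m["precision"] == pytest.approx(94.4, abs=0.05)
        assert m["f_beta"] == pytest.approx(0.894, abs=0.001)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=30, fn=0, fp=0, tn=20))
        for key in ("accuracy", "sensitivity", "specificity", "precision", "g_mean"):
            assert m[key] == 100.0
        assert m["f_beta"] == 1.0

    def test_undefined_marker_not_infinity(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=8))
        assert math.isnan(m["sensitivity"]) and math.isnan(m["f_beta"])

    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_integer_arithmetic_oracle(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        m = compute_metrics(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + fn + fp + tn))
        assert m["accuracy"] + m["misclassification_error"] == pytest.approx(100.0)
        if tp + fn:
            assert m["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert m["specificity"] == pytest.approx(100 * tn / (tn + fp))
        if not math.isnan(m["sensitivity"]) and not math.isnan(m["specificity"]):
            assert m["g_mean"] == pytest.approx(
                math.sqrt(m["sensitivity"] * m["specificity"])
            )

    def test_f1_is_harmonic_mean(self):
        m = compute_metrics(ConfusionMatrix(tp=29, fn=1, fp=3, tn=17))
        p, s = m["precision"] / 100, m["sensitivity"] / 100
        assert m["f_beta"] == pytest.approx(2 * p * s / (p + s), rel=1e-12)

    def test_swapping_classes_swaps_sensitivity_specificity(self):
        cm = ConfusionMatrix(tp=12, fn=4, fp=7, tn=27)
        m1 = compute_metrics(cm)
        m2 = compute_metrics(cm.swapped("other"))
        assert m1["sensitivity"] == m2["specificity"]
        assert m1["specificity"] == m2["sensitivity"]
        assert m1["accuracy"] == m2["accuracy"]


class TestAggregation:
    def test_weighted_and_arithmetic_sensitivity(self):
        per = {
            "normal": {k: float("nan") for k in compute_metrics(
                ConfusionMatrix(1, 0, 0, 1)).keys()},
            "suspicious": {k: float("nan") for k in compute_metrics(
                ConfusionMatrix(1, 0, 0, 1)).keys()},
        }
        per["normal"]["sensitivity"] = 96.7
        per["suspicious"]["sensitivity"] = 85.0
        agg = aggregate_metrics(per, {"normal": 30, "suspicious": 20})
        assert agg["weighted"]["sensitivity"] == pytest.approx(92.0, abs=0.05)
        assert agg["arithmetic"]["sensitivity"] == pytest.approx(90.85, abs=0.05)

    def test_weighted_specificity(self):
        rep = MetricsReport.from_confusion(ConfusionMatrix(tp=29, fn=1, fp=3, tn=17))
        assert rep.overall_weighted["specificity"] == pytest.approx(89.7, abs=0.05)

    def test_equal_values_invariant(self):
        per = {
            "a": dict.fromkeys(compute_metrics(ConfusionMatrix(1, 0, 0, 1)), 77.0),
            "b": dict.fromkeys(compute_metrics(ConfusionMatrix(1, 0, 0, 1)), 77.0),
        }
        agg = aggregate_metrics(per, {"a": 13, "b": 37})
        assert agg["arithmetic"]["accuracy"] == pytest.approx(77.0)
        assert agg["weighted"]["accuracy"] == pytest.approx(77.0)


class TestGMean:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(92.0, 89.7, 90.8), (90.4, 73.9, 81.7), (100.0, 0.0, 0.0)],
    )
    def test_reported_values(self, sens, spec, expected):
        assert g_mean(sens, spec) == pytest.approx(expected, abs=0.05)


def gaussian_clouds(n_pos, n_neg, sep, seed, d=4):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_pos, d)), rng.normal(sep, 1, (n_neg, d))]
    )
    y = np.array(["normal"] * n_pos + ["suspicious"] * n_neg)
    return X, y


class TestCrossValidate:
    def test_well_separated_clouds_high_accuracy(self):
        X, y = gaussian_clouds(30, 20, sep=6.0, seed=0)
        res = cross_validate(X, y, ClassifierConfig(kernel="rbf", seed=0))
        assert res.pooled_report.per_class["normal"]["accuracy"] >= 95.0

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(3)
        X, y = gaussian_clouds(25, 25, sep=0.0, seed=3)
        res = cross_validate(X, y, ClassifierConfig(kernel="rbf", seed=3))
        assert 30.0 <= res.pooled_report.per_class["normal"]["accuracy"] <= 70.0

    def test_every_sample_tested_exactly_once(self):
        X, y = gaussian_clouds(30, 20, sep=3.0, seed=1)
        res = cross_validate(X, y, ClassifierConfig(n_folds=10, seed=1))
        counts = np.bincount(res.fold_of_sample, minlength=10)
        assert counts.sum() == 50 and (res.fold_of_sample >= 0).all()
        assert set(res.fold_of_sample) == set(range(10))

    def test_leave_one_out(self):
        X, y = gaussian_clouds(25, 25, sep=6.0, seed=2)
        res = cross_validate(X, y, ClassifierConfig(n_folds=50, seed=2))
        assert np.bincount(res.fold_of_sample).max() == 1

    def test_seed_reproducibility(self):
        X, y = gaussian_clouds(30, 20, sep=2.0, seed=4)
        r1 = cross_validate(X, y, ClassifierConfig(seed=11))
        r2 = cross_validate(X, y, ClassifierConfig(seed=11))
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        assert r1.pooled_confusion == r2.pooled_confusion

    @pytest.mark.parametrize("kernel", ["linear", "polynomial_degree2", "rbf"])
    def test_all_kernels_run(self, kernel):
        X, y = gaussian_clouds(15, 15, sep=5.0, seed=5)
        res = cross_validate(X, y, ClassifierConfig(kernel=kernel, n_folds=5, seed=5))
        assert res.pooled_confusion.total == 30

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ContractError):
            cross_validate(X, ["normal"] * 10)

    def test_too_many_folds_rejected(self):
        X, y = gaussian_clouds(3, 3, sep=5.0, seed=6)
        with pytest.raises(ContractError):
            cross_validate(X, y, ClassifierConfig(n_folds=7))
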