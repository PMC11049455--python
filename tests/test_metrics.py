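import numpy as np
import pytest

from genegraph.metrics import (MetricsReport, auc_concordance, compute_report,
                               roc_optimal_threshold, specificity_sensitivity)

RNG = np.random.default_rng(123)


class TestConfusionArithmetic:
    def test_hand_computed_two_class_matrix(self):
        # rows = truth (neg, pos): TN=8 FP=2 / FN=1 TP=9
        cm = np.array([[8, 2], [1, 9]])
        spec, sens = specificity_sensitivity(cm)
        assert spec[1] == pytest.approx(0.80)
        assert sens[1] == pytest.approx(0.90)
        assert 100.0 * cm.trace() / cm.sum() == pytest.approx(85.0)

    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1, 1])
        rep = compute_report(y, y, None, ("neg", "pos"))
        assert np.allclose(rep.specificity, 1.0)
        assert np.allclose(rep.sensitivity, 1.0)
        assert rep.accuracy == 100.0 and rep.f1_positive == 1.0

    def test_degenerate_all_one_class_predictor(self):
        y = np.array([0] * 10 + [1] * 10)
        pred = np.zeros(20, dtype=int)
        rep = compute_report(y, pred, None, ("neg", "pos"))
        assert rep.accuracy == pytest.approx(50.0)
        assert rep.sensitivity[1] == 0.0 and rep.sensitivity[0] == 1.0

    def test_accuracy_recomputable_from_stored_confusion(self):
        y = RNG.integers(0, 4, 200)
        pred = RNG.integers(0, 4, 200)
        rep = compute_report(y, pred, None, ("a", "b", "c", "d"))
        assert rep.accuracy == pytest.approx(
            100.0 * rep.confusion.trace() / rep.confusion.sum())
        assert rep.confusion.sum() == 200

    def test_absent_class_rates_are_nan_not_zero(self):
        y = np.array([0, 0, 1, 1])          # class 2/3 absent
        rep = compute_report(y, y, None, ("a", "b", "c", "d"))
        assert np.isnan(rep.sensitivity[2]) and np.isnan(rep.sensitivity[3])
        assert not np.isnan(rep.sensitivity[0])

    def test_binary_label_inversion_swaps_macro_rates(self):
        y = RNG.integers(0, 2, 100)
        pred = RNG.integers(0, 2, 100)
        a = compute_report(y, pred, None, ("n", "p"))
        b = compute_report(1 - y, 1 - pred, None, ("n", "p"))
        assert a.sensitivity[1] == pytest.approx(b.specificity[1])
        assert a.specificity[1] == pytest.approx(b.sensitivity[1])


class TestROC:
    def test_separable_scores_have_unit_J_and_auc(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        truth = np.array([1, 1, 0, 0])
        thr, fpr, tpr, cuts, auc = roc_optimal_threshold(scores, truth)
        assert 0.2 < thr <= 0.8
        j = (tpr - fpr).max()
        assert j == pytest.approx(1.0) and auc == pytest.approx(1.0)

    def test_roc_endpoints_and_monotonicity(self):
        scores = RNG.random(50)
        truth = RNG.integers(0, 2, 50)
        _, fpr, tpr, _, _ = roc_optimal_threshold(scores, truth)
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all()

    def test_random_scores_auc_near_half(self):
        n = 200
        truth = np.r_[np.ones(100, int), np.zeros(100, int)]
        scores = RNG.random(n)
        *_, auc = roc_optimal_threshold(scores, truth)
        se = np.sqrt((100 + 100 + 1) / (12 * 100 * 100))
        assert abs(auc - 0.5) < 3 * se

    def test_score_reversal_antisymmetry(self):
        scores = RNG.random(60)
        truth = RNG.integers(0, 2, 60)
        *_, auc = roc_optimal_threshold(scores, truth)
        *_, auc_rev = roc_optimal_threshold(-scores, truth)
        assert auc_rev == pytest.approx(1.0 - auc)

    def test_curve_auc_equals_concordance(self):
        for trial in range(5):
            rng = np.random.default_rng(trial)
            scores = rng.integers(0, 10, 80) / 10.0      # include ties
            truth = rng.integers(0, 2, 80)
            *_, auc = roc_optimal_threshold(scores, truth)
            assert abs(auc - auc_concordance(scores, truth)) < 1e-9

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_optimal_threshold([0.1, 0.9], [1, 1])

    def test_tie_breaks_toward_higher_specificity(self):
        # two thresholds reach J = 0.5; the lower-FPR one must win
        scores = np.array([0.9, 0.7, 0.7, 0.1])
        truth = np.array([1, 1, 0, 0])
        thr, fpr, tpr, cuts, _ = roc_optimal_threshold(scores, truth)
        j = tpr - fpr
        ties = np.flatnonzero(j == j.max())
        assert fpr[np.flatnonzero(cuts == thr)][0] == fpr[ties].min()


def test_report_serialisation_roundtrip():
    y = RNG.integers(0, 2, 40)
    proba = RNG.random((40, 2))
    proba /= proba.sum(axis=1, keepdims=True)
    rep = compute_report(y, proba.argmax(axis=1), proba, ("n", "p"))
    d = rep.to_dict()
    assert set(d) >= {"classes", "confusion", "accuracy", "auc"}
    assert isinstance(rep.summary(), str) and "Accuracy" in rep.summary()
    assert isinstance(rep, MetricsReport)
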