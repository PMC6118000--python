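"""Confusion-matrix metrics: accuracy, Cohen's kappa, one-vs-rest ROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgposture.evaluate import (
    ConfusionMatrix,
    accuracy,
    cohen_kappa,
    confusion_matrix,
    evaluate_predictions,
    one_vs_rest_metrics,
)
from ecgposture.reference import reference_matrix


def brute_force_kappa(counts: np.ndarray) -> float:
    """Independent oracle: (P_A - P_C) / (1 - P_C) evaluated with exact
    rational arithmetic from explicit per-class loops."""
    from fractions import Fraction

    n = int(counts.sum())
    p_a = Fraction(sum(int(counts[i, i]) for i in range(counts.shape[0])), n)
    p_c = Fraction(0)
    for i in range(counts.shape[0]):
        row = Fraction(sum(int(counts[i, j]) for j in range(counts.shape[1])), n)
        col = Fraction(sum(int(counts[j, i]) for j in range(counts.shape[0])), n)
        p_c += row * col
    return float((p_a - p_c) / (1 - p_c))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = ["left", "supine", "right", "left"]
        cm = confusion_matrix(y, y)
        assert np.trace(cm.counts) == 4
        assert cm.counts.sum() == 4

    def test_hand_counted_example(self):
        cm = confusion_matrix(["left", "supine", "right"],
                              ["left", "left", "right"])
        np.testing.assert_array_equal(
            cm.counts, [[1, 1, 0], [0, 0, 0], [0, 0, 1]])

    def test_total_conserved(self, rng):
        y_true = rng.choice(["left", "supine", "right"], 500)
        y_pred = rng.choice(["left", "supine", "right"], 500)
        assert confusion_matrix(y_true, y_pred).total == 500

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["left"], ["standing"])


class TestAccuracy:
    def test_published_subject_specific_matrix(self):
        cm = reference_matrix("subject_specific")
        assert accuracy(cm) == pytest.approx(3807 / 3899)

    def test_degenerate_cases(self):
        assert accuracy(ConfusionMatrix(np.diag([5, 3, 2]))) == 1.0
        off = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert accuracy(ConfusionMatrix(off)) == 0.0
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((3, 3), dtype=int)))


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(np.diag([5, 3, 2]))) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        row = np.array([6, 3, 1])
        col = np.array([2, 5, 3])
        counts = np.outer(row, col)  # counts[i,j] proportional to row_i * col_j
        assert abs(cohen_kappa(ConfusionMatrix(counts))) < 1e-12

    def test_published_subject_specific_matrix(self):
        cm = reference_matrix("subject_specific")
        assert cohen_kappa(cm) == pytest.approx(0.9616, abs=5e-4)

    def test_single_cell_matrix_undefined(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 10
        assert math.isnan(cohen_kappa(ConfusionMatrix(counts)))

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(1000):
            counts = rng.integers(0, 20, size=(3, 3))
            if counts.sum() == 0 or counts.sum(0).max() == counts.sum():
                continue
            cm = ConfusionMatrix(counts)
            assert cohen_kappa(cm) == brute_force_kappa(counts)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        labels = ["left", "supine", "right"]
        y_true = rng.choice(labels, 300)
        y_pred = np.where(rng.random(300) < 0.6, y_true, rng.choice(labels, 300))
        cm = confusion_matrix(y_true, y_pred)
        assert cohen_kappa(cm) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.permutations([0, 1, 2]))
    def test_invariant_under_class_permutation(self, perm):
        counts = np.array([[50, 5, 2], [3, 40, 6], [1, 7, 30]])
        permuted = counts[np.ix_(perm, perm)]
        assert cohen_kappa(ConfusionMatrix(permuted)) == pytest.approx(
            cohen_kappa(ConfusionMatrix(counts)))


class TestOneVsRest:
    def test_perfectly_ranked_scores(self):
        y = np.array(["left"] * 5 + ["supine"] * 5)
        scores = np.r_[np.linspace(0.6, 1.0, 5), np.linspace(0.0, 0.4, 5)]
        _, _, auc, _ = one_vs_rest_metrics(scores, y, y, "left")
        assert auc == 1.0

    def test_random_scores_auc_half(self, rng):
        y = rng.choice(["left", "supine", "right"], 2000)
        scores = rng.random(2000)
        _, _, auc, _ = one_vs_rest_metrics(scores, y, y, "left")
        assert abs(auc - 0.5) < 0.03

    def test_hard_metric_definitions(self):
        # TP=90 FN=10 TN=80 FP=20
        y_true = np.array(["left"] * 100 + ["supine"] * 100)
        y_pred = np.array(["left"] * 90 + ["supine"] * 10
                          + ["supine"] * 80 + ["left"] * 20)
        scores = (y_pred == "left").astype(float)
        _, _, _, hard = one_vs_rest_metrics(scores, y_true, y_pred, "left")
        assert hard["sensitivity"] == pytest.approx(0.9)
        assert hard["specificity"] == pytest.approx(0.8)
        assert hard["f1"] == pytest.approx(180 / 210)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.choice(["left", "supine"], 500)
        scores = rng.random(500) + (y == "left") * 0.3
        _, _, auc1, _ = one_vs_rest_metrics(scores, y, y, "left")
        _, _, auc2, _ = one_vs_rest_metrics(np.exp(3 * scores), y, y, "left")
        assert auc1 == pytest.approx(auc2)

    def test_absent_positive_class(self):
        y = np.array(["supine"] * 10)
        _, _, auc, hard = one_vs_rest_metrics(np.zeros(10), y, y, "left")
        assert math.isnan(auc) and math.isnan(hard["sensitivity"])


class TestEvaluatePredictions:
    def test_bundle_consistency(self, rng):
        labels = ["left", "supine", "right"]
        y_true = rng.choice(labels, 400)
        y_pred = np.where(rng.random(400) < 0.7, y_true, rng.choice(labels, 400))
        scores = rng.random((400, 3))
        bundle = evaluate_predictions(y_true, y_pred, scores)
        assert bundle.cm.total == 400
        assert 0.0 <= bundle.accuracy <= 1.0
        assert bundle.kappa <= 1.0
        assert set(bundle.per_class) == set(labels)
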