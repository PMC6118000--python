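"""Classifier evaluation: confusion matrices, accuracy, Cohen's kappa and
one-vs-rest ROC metrics.

The confusion-matrix convention is rows = output (predicted) class,
columns = target (true) class. Cohen's kappa is the chance-corrected
agreement

    kappa = (P_A - P_C) / (1 - P_C),

where P_A is the observed accuracy (sum of diagonal proportions) and P_C
the agreement expected from the row/column margins alone; kappa = 1 is
perfect agreement and kappa <= 0 no better than chance. For the
three-class position problem, per-class ROC/AUC, sensitivity, specificity
and F1 are one-vs-rest: the other two positions merge into the negative
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .core import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "MetricsBundle",
    "confusion_matrix",
    "accuracy",
    "cohen_kappa",
    "one_vs_rest_metrics",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with counts[i, j] = #(predicted class i, true class j)."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:  # per output class
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:  # per target class
        return self.counts.sum(axis=0)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("class order mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.class_order)


def confusion_matrix(
    y_true,
    y_pred,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Count predictions: rows = predicted class, columns = true class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correctly classified epochs: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (P_A - P_C) / (1 - P_C).

    P_C sums, over classes, the product of the marginal row and column
    proportions. Degenerate margins (P_C = 1, a single-cell matrix) make
    kappa undefined and return NaN.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    # integer arithmetic with a single final division keeps the value
    # exactly equal to the rational (P_A - P_C) / (1 - P_C)
    trace = int(np.trace(cm.counts))
    margin = int(np.dot(cm.row_sums, cm.col_sums))
    denominator = n * n - margin  # proportional to 1 - P_C
    if denominator == 0:
        return math.nan
    return (n * trace - margin) / denominator


@dataclass
class MetricsBundle:
    """Accuracy, kappa and per-class one-vs-rest metrics for one test set."""

    cm: ConfusionMatrix
    accuracy: float
    kappa: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    roc: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.cm.class_order),
            "confusion_matrix": self.cm.counts.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "per_class": {c: dict(v) for c, v in self.per_class.items()},
        }


def one_vs_rest_metrics(
    scores: np.ndarray,
    y_true,
    y_pred,
    positive_class: str,
) -> tuple[np.ndarray, np.ndarray, float, dict[str, float]]:
    """One-vs-rest ROC and threshold-free/hard metrics for one class.

    ``scores`` are the classifier's scores for ``positive_class`` (here,
    random-forest vote fractions). The ROC sweeps every distinct score;
    AUC is the trapezoid area. Sensitivity, specificity and F1 are
    computed from the hard predictions' 2x2 collapse. Returns
    (fpr, tpr, auc, {sensitivity, specificity, f1}).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_class
    if not pos.any():
        nan = math.nan
        return (np.array([]), np.array([]), nan,
                {"sensitivity": nan, "specificity": nan, "f1": nan})
    if pos.all():
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        auc = math.nan
    else:
        fpr, tpr, _ = roc_curve(pos.astype(int), scores)
        auc = float(np.trapezoid(tpr, fpr))
    tp = int(np.sum(pos & (y_pred == positive_class)))
    fn = int(np.sum(pos & (y_pred != positive_class)))
    tn = int(np.sum(~pos & (y_pred != positive_class)))
    fp = int(np.sum(~pos & (y_pred == positive_class)))
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan
    return fpr, tpr, auc, {"sensitivity": sens, "specificity": spec, "f1": f1}


def evaluate_predictions(
    y_true,
    y_pred,
    scores: np.ndarray | None = None,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> MetricsBundle:
    """Full metrics bundle for one test set.

    ``scores`` is an (n, k) array of per-class scores in ``class_order``
    (optional; without it ROC/AUC are omitted).
    """
    cm = confusion_matrix(y_true, y_pred, class_order)
    bundle = MetricsBundle(cm=cm, accuracy=accuracy(cm), kappa=cohen_kappa(cm))
    for j, cls in enumerate(class_order):
        cls_scores = scores[:, j] if scores is not None else None
        if cls_scores is not None:
            fpr, tpr, auc, hard = one_vs_rest_metrics(cls_scores, y_true, y_pred, cls)
            bundle.roc[cls] = (fpr, tpr)
        else:
            _, _, auc, hard = one_vs_rest_metrics(
                np.asarray(np.asarray(y_pred) == cls, dtype=float),
                y_true, y_pred, cls)
        bundle.per_class[cls] = {"auc": auc, **hard}
    return bundle
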