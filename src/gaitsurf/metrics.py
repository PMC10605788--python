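"""Confusion matrix and multiclass precision/recall/F1/accuracy.

Rows of the confusion matrix are actual classes, columns are predicted
classes, with the class axis in canonical surface order.  Per-class recall
is the row-normalized diagonal, precision the column-normalized diagonal,
and F1 their harmonic mean; 0/0 cases are defined as 0.  Weighted
averages use the actual-class counts (row sums) as weights, which makes
weighted recall algebraically identical to accuracy.  A ``paper_literal_eqs``
flag swaps the precision/recall index orientation for reproducing sources
that transpose it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidLabelError",
    "UndefinedMetricsError",
    "confusion",
    "per_class_metrics",
    "weighted_metrics",
    "row_normalized",
    "MetricsReport",
    "evaluate_predictions",
]


class InvalidLabelError(ValueError):
    """A label falls outside [0, n_classes)."""


class UndefinedMetricsError(ValueError):
    """Metrics requested for an empty confusion matrix."""


def confusion(y_true, y_pred, n_classes: int = 9) -> np.ndarray:
    """Integer count matrix e with e[i, j] = #(true == i and pred == j)."""
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise InvalidLabelError(
                f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (yt, yp), 1)
    return cm


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)


def per_class_metrics(
    cm: np.ndarray, paper_literal_eqs: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (precision, recall, F1).

    With rows = actual: recall_i = e_ii / row_sum_i and precision_i =
    e_ii / col_sum_i.  ``paper_literal_eqs=True`` swaps the two
    normalizations (transposed index convention).
    """
    cm = np.asarray(cm, dtype=float)
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    re = _safe_div(diag, row)
    pr = _safe_div(diag, col)
    if paper_literal_eqs:
        pr, re = re, pr
    f1 = _safe_div(2 * pr * re, pr + re)
    return pr, re, f1


def weighted_metrics(
    cm: np.ndarray, paper_literal_eqs: bool = False
) -> tuple[float, float, float, float]:
    """Weighted (precision, recall, F1) and accuracy.

    Weights are the actual-class counts (row sums); accuracy is
    trace / total.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise UndefinedMetricsError("empty confusion matrix")
    pr, re, f1 = per_class_metrics(cm, paper_literal_eqs=paper_literal_eqs)
    w = cm.sum(axis=1) / total
    acc = np.trace(cm) / total
    return float(w @ pr), float(w @ re), float(w @ f1), float(acc)


def row_normalized(cm: np.ndarray) -> np.ndarray:
    """Each row divided by its sum (all-zero rows stay zero).

    The diagonal equals per-class recall.
    """
    cm = np.asarray(cm, dtype=float)
    row = cm.sum(axis=1, keepdims=True)
    return np.where(row > 0, cm / np.where(row > 0, row, 1), 0.0)


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class and weighted metrics."""

    confusion_matrix: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "accuracy": self.accuracy,
        }


def evaluate_predictions(
    y_true, y_pred, n_classes: int = 9, paper_literal_eqs: bool = False
) -> MetricsReport:
    """Full report from paired label sequences."""
    cm = confusion(y_true, y_pred, n_classes=n_classes)
    pr, re, f1 = per_class_metrics(cm, paper_literal_eqs=paper_literal_eqs)
    wpr, wre, wf1, acc = weighted_metrics(cm, paper_literal_eqs=paper_literal_eqs)
    return MetricsReport(
        confusion_matrix=cm,
        precision=pr,
        recall=re,
        f1=f1,
        weighted_precision=wpr,
        weighted_recall=wre,
        weighted_f1=wf1,
        accuracy=acc,
    )
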