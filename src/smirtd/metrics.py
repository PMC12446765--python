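"""The nine evaluation metrics (accuracy, recall, precision, MCC, balanced
accuracy, F1, AUROC, AUPRC, specificity) and the PRR-ranked recall curve.

Threshold metrics are direct confusion-matrix arithmetic; AUROC and AUPRC
delegate to scikit-learn (average precision uses step interpolation, which the
PR area here deliberately matches).  The positive class is always "has the
ADR" (label 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "threshold_metrics",
    "auroc",
    "auprc",
    "full_report",
    "prr_ranked_recall",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("confusion counts are all zero")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    mcc: float
    bacc: float
    f1: float
    specificity: float
    auroc: Optional[float] = None
    auprc: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "mcc": self.mcc,
            "bacc": self.bacc,
            "f1": self.f1,
            "specificity": self.specificity,
            "auroc": self.auroc,
            "auprc": self.auprc,
        }


def confusion_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def threshold_metrics(counts: ConfusionCounts) -> MetricsReport:
    """The seven threshold-dependent metrics from a confusion table.

    Zero-denominator conventions: precision is 0 (with a warning) when nothing
    is predicted positive; MCC is 0 when any factor of its denominator is 0.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    recall = tp / (tp + fn) if tp + fn else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no predicted positives; precision set to 0")
        precision = 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    bacc = (recall + specificity) / 2.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(accuracy, recall, precision, mcc, bacc, f1, specificity)


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve = P(random positive outscores a random
    negative), ties counted one half."""
    y = np.asarray(labels, dtype=int)
    _check_two_class(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    y = np.asarray(labels, dtype=int)
    if not np.any(y == 1):
        raise ValueError("at least one positive is required")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def full_report(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> MetricsReport:
    """All nine metrics; ``scores`` rank toward the positive class (label 1)."""
    base = threshold_metrics(confusion_from_predictions(y_true, y_pred))
    if scores is None:
        return base
    return MetricsReport(
        **{**base.as_dict(), "auroc": auroc(scores, y_true), "auprc": auprc(scores, y_true)}
    )


def prr_ranked_recall(
    predicted_positive: Sequence[int], group_size: int = 10
) -> list[tuple[int, float]]:
    """Recall curve over drugs pre-sorted by PRR, descending.

    ``predicted_positive[i]`` is 1 when the model predicted the i-th-ranked
    drug positive.  Step k reports (n, recall) with n = min(k*group_size,
    total): the fraction of the top-n drugs predicted positive (all ranked
    drugs carry the ADR signal, so predicted positives are the recalled ones).
    The final partial group is included.
    """
    flags = np.asarray(predicted_positive, dtype=int)
    if flags.size == 0:
        raise ValueError("empty input")
    steps = []
    n = group_size
    while True:
        n = min(n, flags.size)
        steps.append((n, float(flags[:n].sum()) / n))
        if n == flags.size:
            break
        n += group_size
    return steps
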