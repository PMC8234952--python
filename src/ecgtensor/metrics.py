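"""Confusion-matrix metrics and ROC/AUROC for anomaly-detection evaluation.

Accuracy = (TP + TN) / (TP + FP + TN + FN), precision = TP / (TP + FP),
recall = TP / (TP + FN), and the F-score is the harmonic mean of precision
and recall.  AUROC is the rank-based (Mann-Whitney) area, ties counted 0.5,
delegated to scikit-learn; a zero denominator yields 0 with a warning rather
than an exception so that degenerate conditions still produce a row in
experiment tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ConfusionCounts", "MetricSet", "compute_metrics", "auroc", "confusion_from_flags"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    auroc: float | None = None


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_from_flags(flags: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Counts from boolean predictions (``flags``) and boolean truth (``labels``)."""
    flags = np.asarray(flags, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(flags & labels)),
        fp=int(np.sum(flags & ~labels)),
        tn=int(np.sum(~flags & ~labels)),
        fn=int(np.sum(~flags & labels)),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f_score = _safe_div(2 * precision * recall, precision + recall, "f_score")
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f_score=f_score)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC; ties contribute 0.5.  Both classes must be present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, scores))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) curve points, monotone in FPR."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr
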