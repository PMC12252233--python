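"""Classification metrics, ROC-AUC and cross-validation splitting.

Positive class throughout is class 1 (opacity / pneumonia). Metrics with a
zero denominator are reported as ``None`` with a warning rather than being
silently coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "compute_metrics",
    "auc_roc",
    "kfold_split",
    "summarize_folds",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics; undefined ratios are None."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2PR/(P+R).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (no predicted positives)", stacklevel=2)
        precision = None
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (no actual positives)", stacklevel=2)
        recall = None
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        if precision is not None and recall is not None:
            warnings.warn("F1 undefined (precision + recall = 0)", stacklevel=2)
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based area under the ROC curve, ties averaged.

    Equivalent to the normalized Mann-Whitney two-sample rank statistic:
    the probability that a random positive outscores a random negative,
    counting ties as one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_roc requires both classes to be present")
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def kfold_split(
    n_items: int, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled, near-equal, disjoint folds covering all items.

    Deterministic for a fixed seed; fold sizes differ by at most one, with
    the larger folds first.
    """
    if n_items < k:
        raise ValueError(f"need n_items >= k, got {n_items} < {k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in kf.split(np.arange(n_items))]


def summarize_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +/- sample standard deviation of per-fold metrics."""
    if not reports:
        raise ValueError("no fold reports to summarize")
    frame = pd.DataFrame([r.to_dict() for r in reports]).astype(float)
    out = pd.DataFrame({"mean": frame.mean(), "std": frame.std(ddof=1)})
    return out
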