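"""Binary-classification metrics for PPI evaluation.

Accuracy, recall, precision and F1 are computed from threshold confusion
counts; AUC is the rank-based (Mann-Whitney) statistic with half-credit for
ties.  Edge conventions: a score exactly at the threshold counts as a
positive prediction, and a metric whose denominator is zero returns 0 with a
warning rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts of scores thresholded at `threshold` (>= is positive)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if y.shape != s.shape:
        raise ValueError(f"labels shape {y.shape} != scores shape {s.shape}")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _safe_div(c.TP + c.TN, c.total, "accuracy")


def recall(c: ConfusionCounts) -> float:
    return _safe_div(c.TP, c.TP + c.FN, "recall")


def precision(c: ConfusionCounts) -> float:
    return _safe_div(c.TP, c.TP + c.FP, "precision")


def f1(c: ConfusionCounts) -> float:
    return _safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN, "f1")


def auc(labels, scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks give ties half credit
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def evaluate(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """All five metrics as a dict (accuracy/recall/precision/f1/auc)."""
    c = confusion(labels, scores, threshold)
    return {
        "accuracy": accuracy(c),
        "recall": recall(c),
        "precision": precision(c),
        "f1": f1(c),
        "auc": auc(labels, scores),
    }
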