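"""Binary-classification performance measures and score-to-rank conversion.

Measures are reported on [0, 1]; a measure whose denominator is empty (e.g.
sensitivity when no positives were evaluated) is returned as NaN — an explicit
"undefined" flag, never silently 0.  AUC uses the tie-corrected Mann-Whitney
rank form, which matters here because ensemble vote proportions live on a grid
of N+1 values and tie heavily.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "roc_auc",
    "rank_algorithms",
    "is_defined",
]

UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    """True unless ``x`` is the NaN flag for an undefined measure."""
    return not math.isnan(x)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion-matrix cells with the positive class as "class 1".

    a: true positive, b: false positive, c: false negative, d: true negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _infer_positive(labels: np.ndarray, positive_class):
    classes = np.unique(labels)
    if len(classes) > 2:
        raise ValueError(f"expected at most two classes, got {len(classes)}")
    if positive_class is None:
        return classes[-1]  # larger label plays "class 1"
    return positive_class


def confusion(y_true, y_pred, positive_class=None) -> ConfusionCounts:
    """Count the 2x2 confusion cells of a binary prediction set.

    ``positive_class`` defaults to the numerically/lexicographically larger
    label observed in ``y_true`` and ``y_pred`` combined.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from zero samples")
    pos = _infer_positive(np.concatenate([y_true, y_pred]), positive_class)
    tp = y_true == pos
    pp = y_pred == pos
    return ConfusionCounts(
        a=int(np.sum(tp & pp)),
        b=int(np.sum(~tp & pp)),
        c=int(np.sum(tp & ~pp)),
        d=int(np.sum(~tp & ~pp)),
    )


def accuracy(cc: ConfusionCounts) -> float:
    """(a + d) / n; NaN for an empty count set."""
    return (cc.a + cc.d) / cc.total if cc.total else UNDEFINED


def sensitivity(cc: ConfusionCounts) -> float:
    """True-positive rate a / (a + c); NaN when no positives were evaluated."""
    den = cc.a + cc.c
    return cc.a / den if den else UNDEFINED


def specificity(cc: ConfusionCounts) -> float:
    """True-negative rate d / (b + d); NaN when no negatives were evaluated."""
    den = cc.b + cc.d
    return cc.d / den if den else UNDEFINED


def roc_auc(y_true, scores, positive_class=None) -> float:
    """Area under the ROC curve via the tie-corrected rank statistic.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative, counting exact ties as 1/2: with midranks R_i,
    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    1 for perfect separation, ~0.5 for scores independent of the labels.
    Returns NaN if only one class is present.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    pos = _infer_positive(y_true, positive_class)
    mask = y_true == pos
    n_pos = int(mask.sum())
    n_neg = int((~mask).sum())
    if n_pos == 0 or n_neg == 0:
        return UNDEFINED
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rank_algorithms(
    scores: Mapping[Hashable, float],
    higher_better: bool = True,
    rng=None,
) -> tuple:
    """Order algorithm identifiers by score, best first.

    Undefined (NaN) scores rank last.  Exact ties are broken by a seeded
    random shuffle within the tied block — a fixed preference order would
    systematically favor one algorithm across thousands of bootstrap rounds.
    """
    if not scores:
        raise ValueError("empty score set")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ids = list(scores)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]

    def key(item):
        v = float(scores[item])
        if math.isnan(v):
            return (1, 0.0)
        return (0, -v if higher_better else v)

    return tuple(sorted(shuffled, key=key))  # stable: ties keep shuffled order
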