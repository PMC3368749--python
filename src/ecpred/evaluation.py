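"""Multi-class evaluation metrics and the fold-wise permutation test.

Performance is summarised from a K x K confusion matrix: overall accuracy,
per-class accuracy (class recall), and Gorodkin's K-category correlation
coefficient R_K — the multi-class generalisation of the Matthews
correlation coefficient, which gives a class-balance-aware view of the
same predictions.

Two classifiers evaluated on the same cross-validation folds are compared
with an exact sign-permutation test: with d_i the difference in correct
predictions on fold i, the observed statistic D_0 = sum(d_i) is ranked
among all 2^F sign assignments sum(+-d_i).  The two-sided p-value is
n / 2^F where n counts permutations at least as extreme as D_0; n can
never be below 2 because both D_0 and -D_0 occur among the permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "FoldOutcome",
    "PermutationResult",
    "confusion_matrix",
    "accuracy",
    "per_class_accuracy",
    "gorodkin_rk",
    "permutation_test",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted, labels 1..K."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels: Sequence[int], predicted_labels: Sequence[int],
                     n_classes: int) -> ConfusionMatrix:
    """Tally (true, predicted) pairs for labels in 1..n_classes."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label lists have different lengths")
    if t.size == 0:
        return ConfusionMatrix(np.zeros((n_classes, n_classes), dtype=np.int64))
    for arr, which in ((t, "true"), (p, "predicted")):
        if arr.min() < 1 or arr.max() > n_classes:
            raise ValueError(f"{which} labels outside 1..{n_classes}")
    return ConfusionMatrix(_sk_confusion(t, p, labels=np.arange(1, n_classes + 1)))


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of predictions that are correct (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix has no accuracy")
    return float(np.trace(cm.counts)) / cm.total


def per_class_accuracy(cm: ConfusionMatrix) -> Dict[int, Optional[float]]:
    """Class recall for each class 1..K; None for classes absent from truth."""
    out: Dict[int, Optional[float]] = {}
    row_totals = cm.counts.sum(axis=1)
    for k in range(cm.n_classes):
        out[k + 1] = (float(cm.counts[k, k]) / row_totals[k]) if row_totals[k] else None
    return out


def gorodkin_rk(cm: ConfusionMatrix) -> float:
    """Gorodkin's K-category correlation coefficient R_K.

    With N predictions, row sums t_k, column sums p_k and trace c:

        R_K = (N c - sum_k t_k p_k)
              / sqrt((N^2 - sum_k p_k^2) (N^2 - sum_k t_k^2))

    Returns 0 when a denominator factor vanishes (all truth or all
    prediction in one class).  Equals the Matthews correlation coefficient
    on 2 x 2 tables.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix has no correlation")
    counts = cm.counts.astype(float)
    n = counts.sum()
    t = counts.sum(axis=1)
    p = counts.sum(axis=0)
    c = np.trace(counts)
    cov = n * c - float(t @ p)
    denom_p = n * n - float(p @ p)
    denom_t = n * n - float(t @ t)
    if denom_p <= 0 or denom_t <= 0:
        return 0.0
    return cov / np.sqrt(denom_p * denom_t)


@dataclass
class FoldOutcome:
    """Per-fold correct-prediction counts for one classifier."""

    correct: List[int]
    sizes: List[int]

    def __post_init__(self) -> None:
        if len(self.correct) != len(self.sizes):
            raise ValueError("correct counts and fold sizes differ in length")
        for c, s in zip(self.correct, self.sizes):
            if not 0 <= c <= s:
                raise ValueError(f"correct count {c} outside fold size {s}")

    @property
    def n_folds(self) -> int:
        return len(self.correct)


@dataclass
class PermutationResult:
    """Observed difference D_0, all permuted differences, and p = n / 2^F."""

    d0: int
    permuted: np.ndarray
    n: int
    p: float
    sidedness: str = "two-sided"


def permutation_test(a: FoldOutcome, b: FoldOutcome,
                     sidedness: str = "two-sided") -> PermutationResult:
    """Exact sign-permutation test for paired fold outcomes.

    All 2^F sign assignments of the fold differences are enumerated
    (F <= 20).  Two-sided (default): n = #{|D_p| >= |D_0|}; one-sided:
    n = #{D_p >= D_0}.  Equality counts toward n, so zero-difference folds
    never reduce it.
    """
    if a.n_folds != b.n_folds or a.sizes != b.sizes:
        raise ValueError("fold structures do not match")
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    f = a.n_folds
    if f == 0:
        raise ValueError("no folds to permute")
    if f > 20:
        raise ValueError("exhaustive enumeration limited to 20 folds")
    d = np.asarray(a.correct, dtype=np.int64) - np.asarray(b.correct, dtype=np.int64)
    d0 = int(d.sum())
    signs = ((np.arange(2 ** f)[:, None] >> np.arange(f)) & 1) * 2 - 1
    permuted = signs @ d
    if sidedness == "two-sided":
        n = int(np.count_nonzero(np.abs(permuted) >= abs(d0)))
    else:
        n = int(np.count_nonzero(permuted >= d0))
    return PermutationResult(d0=d0, permuted=permuted, n=n,
                             p=n / float(2 ** f), sidedness=sidedness)
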