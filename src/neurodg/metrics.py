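"""Evaluation formulas and the stratified cross-validation harness.

The confusion matrix is fixed with **rows = true class, columns = predicted
class**. With t_k the true occurrences of class k (row sums), p_k its
predicted occurrences (column sums), c the correct total (trace) and s the
grand total, the two headline metrics are

    macro F1 = (1/K) * sum_k 2 P_k R_k / (P_k + R_k),
        P_k = M_kk / p_k,  R_k = M_kk / t_k,

    MCC = (c s - sum_k p_k t_k) / sqrt((s^2 - sum_k p_k^2)(s^2 - sum_k t_k^2)),

with the usual zero-division conventions (a degenerate class contributes
F1_k = 0; MCC is defined as 0 when either square-root factor vanishes).
Cross-validation uses stratified k-fold with a rolling validation fold,
giving the 3:1:1 train/validation/test ratio at k = 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["ConfusionMatrix", "SplitPlan", "confusion", "macro_f1", "mcc",
           "stratified_kfold", "per_class_precision_recall"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (M < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "M", M.astype(np.int64))

    @property
    def K(self) -> int:
        return self.M.shape[0]

    @property
    def t(self) -> np.ndarray:
        """True occurrences per class (row sums)."""
        return self.M.sum(axis=1)

    @property
    def p(self) -> np.ndarray:
        """Predicted occurrences per class (column sums)."""
        return self.M.sum(axis=0)

    @property
    def c(self) -> int:
        """Correctly predicted total (trace)."""
        return int(np.trace(self.M))

    @property
    def s(self) -> int:
        """Total count."""
        return int(self.M.sum())


def confusion(labels, predictions, K: int) -> ConfusionMatrix:
    """Count matrix M[true, predicted] from paired label/prediction vectors."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    if y.size and (y.min() < 0 or y.max() >= K or yhat.min() < 0 or yhat.max() >= K):
        raise ValueError(f"class ids must lie in 0..{K - 1}")
    M = np.zeros((K, K), dtype=np.int64)
    np.add.at(M, (y, yhat), 1)
    return ConfusionMatrix(M)


def per_class_precision_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Standard precision (over predicted counts) and recall (over true counts)."""
    M = cm.M.astype(np.float64)
    diag = np.diag(M)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cm.p > 0, diag / np.maximum(cm.p, 1), 0.0)
        recall = np.where(cm.t > 0, diag / np.maximum(cm.t, 1), 0.0)
    return precision, recall


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of the per-class F1 score, in [0, 1]."""
    precision, recall = per_class_precision_recall(cm)
    denom = precision + recall
    f1 = np.where(denom > 0, 2.0 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    return float(f1.mean())


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient, in [-1, 1].

    Symmetric in the true/predicted roles; 0 by convention when a
    square-root factor is zero (e.g. all predictions in one class).
    """
    t = cm.t.astype(np.float64)
    p = cm.p.astype(np.float64)
    s = float(cm.s)
    c = float(cm.c)
    cov = c * s - float(p @ t)
    f1 = s * s - float(p @ p)
    f2 = s * s - float(t @ t)
    if f1 <= 0.0 or f2 <= 0.0:
        return 0.0
    return cov / np.sqrt(f1 * f2)


@dataclass(frozen=True)
class SplitPlan:
    """k folds of disjoint (train, validation, test) index arrays.

    Fold f uses stratified fold f as its test set, fold (f+1) mod k as its
    validation set and the remaining k-2 folds for training — a 3:1:1 ratio
    at k = 5.
    """

    folds: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    k: int
    seed: int

    def __iter__(self):
        return iter(self.folds)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified k-fold split plan with a rolling validation fold.

    Within each of the k folds the per-class proportions match the full
    label vector to within one sample. Every class must have at least k
    members.
    """
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y)
    small = np.flatnonzero((counts > 0) & (counts < k))
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    test_folds = [test for _, test in skf.split(np.zeros_like(y), y)]
    folds = []
    for f in range(k):
        test = np.sort(test_folds[f])
        val = np.sort(test_folds[(f + 1) % k])
        train = np.sort(np.concatenate([test_folds[g] for g in range(k)
                                        if g != f and g != (f + 1) % k]))
        folds.append((train, val, test))
    return SplitPlan(tuple(folds), k=k, seed=seed)
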