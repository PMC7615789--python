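"""Evaluation protocol: cross-validated classifier metrics and the
nonparametric tests used to compare feature-selection algorithms.

Metrics (ACC, macro Recall, macro F-measure, multiclass MCC) come from one
confusion matrix pooled over stratified k-fold predictions. Algorithm
comparisons use tie-averaged rank tables, the Wilcoxon signed-rank test with
exact two-sided critical values, and the Friedman test with its
Iman-Davenport F transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .io import DataMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "RankTable",
    "crossval_scores",
    "mcc",
    "rank_algorithms",
    "wilcoxon_signed_rank",
    "wilcoxon_critical_value",
    "friedman_test",
]


@dataclass
class ConfusionMatrix:
    """c x c count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    acc: float  # in [0, 1]
    recall_macro: float
    f_macro: float
    mcc: float
    fs: int  # number of retained features evaluated
    acc_over_fs: float  # acc as a percentage divided by fs


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (the R_k statistic).

    Reduces to the classical binary formula for two classes; returns 0 when
    a denominator term vanishes (e.g. all predictions in one class).
    """
    C = cm.counts.astype(float)
    s = C.sum()
    if s == 0:
        raise ValueError("empty confusion matrix")
    t = C.sum(axis=1)  # true-class totals
    p = C.sum(axis=0)  # predicted-class totals
    correct = np.trace(C)
    numerator = correct * s - float(t @ p)
    denom = math.sqrt(s * s - float(p @ p)) * math.sqrt(s * s - float(t @ t))
    if denom == 0:
        return 0.0
    return float(numerator / denom)


def _metrics_from_cm(cm: ConfusionMatrix, fs: int) -> EvaluationReport:
    C = cm.counts.astype(float)
    s = C.sum()
    acc = float(np.trace(C) / s)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall_per = np.where(C.sum(axis=1) > 0, np.diag(C) / C.sum(axis=1), 0.0)
        precision_per = np.where(C.sum(axis=0) > 0, np.diag(C) / C.sum(axis=0), 0.0)
        f_per = np.where(
            recall_per + precision_per > 0,
            2 * recall_per * precision_per / (recall_per + precision_per),
            0.0,
        )
    return EvaluationReport(
        acc=acc,
        recall_macro=float(recall_per.mean()),
        f_macro=float(f_per.mean()),
        mcc=mcc(cm),
        fs=fs,
        acc_over_fs=acc * 100.0 / fs,
    )


def crossval_scores(
    X_reduced: DataMatrix | np.ndarray,
    labels: np.ndarray,
    classifier: str = "tree",
    folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold CV with a decision tree or Adaboost; pooled metrics.

    Predictions from all folds are pooled into a single confusion matrix and
    every metric is computed from it. When the rarest class has fewer members
    than ``folds``, the fold count is reduced (with a warning).
    """
    values = X_reduced.values if isinstance(X_reduced, DataMatrix) else np.asarray(X_reduced, dtype=float)
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if y.shape[0] != values.shape[0]:
        raise ValueError("label length must match the number of samples")
    _, class_counts = np.unique(y, return_counts=True)
    min_count = int(class_counts.min())
    if min_count < folds:
        logger.warning("crossval_scores: rarest class has %d members; reducing folds %d -> %d", min_count, folds, max(2, min_count))
        folds = max(2, min_count)
    if classifier == "tree":
        make_clf = lambda: DecisionTreeClassifier(criterion="entropy", random_state=seed)
    elif classifier == "boost":
        make_clf = lambda: AdaBoostClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier {classifier!r} (expected 'tree' or 'boost')")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for train, test in skf.split(values, y):
        clf = make_clf()
        clf.fit(values[train], y[train])
        y_true_all.append(y[test])
        y_pred_all.append(clf.predict(values[test]))
    cm = ConfusionMatrix(
        sk_confusion_matrix(np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=classes)
    )
    return _metrics_from_cm(cm, fs=values.shape[1])


@dataclass
class RankTable:
    """Per-block tie-averaged ranks of k algorithms; rank 1 is the best score."""

    scores: np.ndarray
    ranks: np.ndarray
    avg_ranks: np.ndarray


def rank_algorithms(scores: np.ndarray, higher_is_better: bool = True) -> RankTable:
    """Tie-averaged rank of each algorithm within each block (row)."""
    scores = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    signed = -scores if higher_is_better else scores
    ranks = np.vstack([rankdata(row, method="average") for row in signed])
    return RankTable(scores=scores, ranks=ranks, avg_ranks=ranks.mean(axis=0))


def wilcoxon_critical_value(m: int, alpha: float = 0.05) -> int:
    """Exact two-sided critical value for the signed-rank statistic.

    Largest c with 2 * P(T <= c) <= alpha under the null, where T sums a
    uniformly random subset of the ranks 1..m. Returns -1 when no rejection
    is possible at this m and alpha.
    """
    if m < 1:
        raise ValueError("m must be positive")
    max_sum = m * (m + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=object)
    counts[0] = 1
    for r in range(1, m + 1):
        counts[r:] = counts[r:] + counts[:-r].copy()
    cdf = np.cumsum(counts) / (2**m)
    crit = -1
    for c in range(max_sum + 1):
        if 2 * cdf[c] <= alpha:
            crit = c
        else:
            break
    return crit


def wilcoxon_signed_rank(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    critical_value: int | None = None,
) -> tuple[float, float, bool]:
    """Paired Wilcoxon signed-rank test; returns (R+, R-, reject).

    Zero differences are dropped; absolute differences get tie-averaged
    ranks; the null of equal performance is rejected when min(R+, R-) is at
    or below the exact two-sided critical value (overridable).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    m = d.size
    if m == 0:
        logger.warning("wilcoxon_signed_rank: all differences zero; no decision")
        return 0.0, 0.0, False
    ranks = rankdata(np.abs(d), method="average")
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    crit = wilcoxon_critical_value(m, alpha) if critical_value is None else critical_value
    reject = min(r_plus, r_minus) <= crit
    return r_plus, r_minus, reject


def friedman_test(scores: np.ndarray) -> dict:
    """Friedman chi-square over N blocks x k algorithms, plus Iman-Davenport F.

    chi_f = 12N/(k(k+1)) * sum_j Rbar_j^2 - 3N(k+1) from tie-averaged
    average ranks; f_f = (N-1) chi_f / (N(k-1) - chi_f). Degrees of freedom
    are (k-1) and (k-1)(N-1).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need an N x k score matrix with N >= 2, k >= 2")
    N, k = scores.shape
    table = rank_algorithms(scores, higher_is_better=True)
    rbar = table.avg_ranks
    chi_f = 12.0 * N / (k * (k + 1)) * float((rbar**2).sum()) - 3.0 * N * (k + 1)
    denom = N * (k - 1) - chi_f
    if denom == 0:
        logger.warning("friedman_test: Iman-Davenport denominator is zero; F is infinite")
        f_f = math.inf
    else:
        f_f = (N - 1) * chi_f / denom
    return {
        "chi_f": chi_f,
        "f_f": f_f,
        "df1": k - 1,
        "df2": (k - 1) * (N - 1),
        "avg_ranks": rbar,
    }
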