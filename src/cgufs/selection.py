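"""The CGUFS selection core.

Within each feature group, the member most informative about the sample
pseudo-labels becomes the *main* feature. Every other member q is compared
against it: if q tells the pseudo-labels more than the main feature tells q
(IG(q, Cluster) > IG(main, q)) it is a *potential effective* feature worth
keeping as a candidate; otherwise the main feature is q's approximate Markov
blanket and q is *potential redundant* and removed. The overall budget
N_new = max(1, floor(beta * d)) is apportioned to groups in proportion to
their symmetric-uncertainty mass, and each group retains its top-quota
candidates by SU rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .adaptive_kmeans import adaptive_kmeans
from .info_measures import RelevanceTable, build_relevance_table
from .io import DataMatrix
from .spectral import FeatureGrouping, group_features

logger = logging.getLogger(__name__)

__all__ = [
    "GroupAnalysis",
    "SelectionBudget",
    "SelectionResult",
    "select_main_feature",
    "classify_group_features",
    "total_budget",
    "group_quotas",
    "rank_and_retain",
    "run_cgufs",
]


@dataclass
class GroupAnalysis:
    """One feature group split into main / effective / redundant members."""

    group_id: int
    member_indices: list[int]
    main_index: int
    effective_indices: list[int]
    redundant_indices: list[int]

    @property
    def retainable(self) -> list[int]:
        return [self.main_index] + self.effective_indices


@dataclass
class SelectionBudget:
    beta: float
    n_new: int
    group_quotas: np.ndarray


@dataclass
class SelectionResult:
    retained_indices: list[int]
    budget: SelectionBudget
    groups: list[GroupAnalysis]
    relevance: RelevanceTable
    pseudo_labels: np.ndarray
    feature_groups: FeatureGrouping


def select_main_feature(group: list[int], relevance: RelevanceTable) -> int:
    """The group member with maximal IG with the pseudo-labels (ties: smallest index)."""
    if not group:
        raise ValueError("empty feature group")
    members = sorted(group)
    ig = relevance.ig_cluster[members]
    return members[int(np.argmax(ig))]  # argmax takes the first (= smallest index) on ties


def classify_group_features(
    group: list[int], main: int, relevance: RelevanceTable
) -> tuple[list[int], list[int]]:
    """Split non-main members into effective and redundant sets.

    A member q is redundant when IG(q, Cluster) < IG(main, q) -- the main
    feature subsumes what q says about the pseudo-labels (approximate Markov
    blanket). Equality keeps q as an effective candidate; SU ranking and the
    quota still filter it downstream.
    """
    if main not in group:
        raise ValueError("main feature must belong to the group")
    effective: list[int] = []
    redundant: list[int] = []
    for q in sorted(group):
        if q == main:
            continue
        ig_qc = relevance.ig_cluster[q]
        ig_pq = relevance.feature_pair_ig(main, q)
        if ig_qc < ig_pq:
            redundant.append(q)
        else:
            effective.append(q)
    return effective, redundant


def total_budget(d: int, beta: float) -> int:
    """N_new = max(1, floor(beta * d))."""
    if not 0 < beta <= 1:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return max(1, math.floor(beta * d))


def group_quotas(groups: list[GroupAnalysis], relevance: RelevanceTable, n_new: int) -> np.ndarray:
    """Apportion the feature budget across groups by SU mass.

    Raw quota of group j is (group SU sum / total SU) * n_new, integerized by
    the largest-remainder method; each quota is capped at the group's count
    of retainable members (main + effective) with the surplus redistributed
    in remainder order. When the total SU mass is zero, quotas fall back to
    group sizes.
    """
    if n_new < 1:
        raise ValueError("n_new must be at least 1")
    su_sums = np.array([relevance.su_cluster[g.member_indices].sum() for g in groups], dtype=float)
    total = su_sums.sum()
    if total <= 0:
        su_sums = np.array([len(g.member_indices) for g in groups], dtype=float)
        total = su_sums.sum()
    raw = su_sums / total * n_new
    caps = np.array([len(g.retainable) for g in groups], dtype=int)
    quotas = np.minimum(np.floor(raw).astype(int), caps)
    remainders = raw - np.floor(raw)
    # largest-remainder top-up (capped groups skipped, surplus cycles onward)
    target = min(n_new, int(caps.sum()))
    order = np.lexsort((np.arange(len(groups)), -remainders))
    while quotas.sum() < target:
        for idx in order:
            if quotas.sum() >= target:
                break
            if quotas[idx] < caps[idx]:
                quotas[idx] += 1
    return quotas


def rank_and_retain(
    groups: list[GroupAnalysis], quotas: np.ndarray, relevance: RelevanceTable
) -> list[int]:
    """Per group, keep the top-quota candidates by SU with the pseudo-labels.

    Candidates are the main feature plus the effective set, ranked by SU
    descending; the main feature wins SU ties, other ties break toward the
    smaller index. Redundant members are never retained.
    """
    retained: list[int] = []
    for g, quota in zip(groups, quotas):
        candidates = sorted(
            g.retainable,
            key=lambda j: (-relevance.su_cluster[j], 0 if j == g.main_index else 1, j),
        )
        retained.extend(candidates[: int(quota)])
    return sorted(retained)


def run_cgufs(
    X: DataMatrix,
    k1: int = 10,
    k2: int = 10,
    beta: float = 0.05,
    bins: int = 5,
    sigma: float | str = "auto",
    seed: int = 0,
    restarts: int = 10,
    n_features: int | None = None,
) -> SelectionResult:
    """Full clustering-guided unsupervised feature selection pipeline.

    Stages: (1) adaptive k-means on samples gives pseudo-labels; (2) features
    are discretized and scored against the pseudo-labels; (3) spectral
    grouping partitions the features; (4) each group is split into main /
    effective / redundant members; (5) the budget (``beta`` fraction of d, or
    the absolute ``n_features`` override) is apportioned and the top-ranked
    candidates retained. Deterministic given ``seed``.
    """
    n, d = X.shape
    k1_eff = min(k1, n)
    assign, trace = adaptive_kmeans(X.values, k1=k1_eff, seed=seed, restarts=restarts)
    logger.info("run_cgufs: %d sample cluster(s) via %s", assign.k, trace.rule_used.value)

    relevance = build_relevance_table(X.values, assign.labels, bins=bins)

    grouping = group_features(X.values, k2=min(k2, d), seed=seed + 100003, sigma=sigma, restarts=restarts)
    logger.info("run_cgufs: %d feature group(s)", grouping.u2)

    groups: list[GroupAnalysis] = []
    for gid in range(grouping.u2):
        members = sorted(np.nonzero(grouping.group_labels == gid)[0].tolist())
        main = select_main_feature(members, relevance)
        effective, redundant = classify_group_features(members, main, relevance)
        groups.append(
            GroupAnalysis(
                group_id=gid,
                member_indices=members,
                main_index=main,
                effective_indices=effective,
                redundant_indices=redundant,
            )
        )

    n_new = n_features if n_features is not None else total_budget(d, beta)
    n_new = max(1, min(n_new, d))
    quotas = group_quotas(groups, relevance, n_new)
    retained = rank_and_retain(groups, quotas, relevance)
    logger.info(
        "run_cgufs: retained %d/%d features (budget %d; quotas %s)",
        len(retained), d, n_new, quotas.tolist(),
    )
    budget = SelectionBudget(beta=beta, n_new=n_new, group_quotas=quotas)
    return SelectionResult(
        retained_indices=retained,
        budget=budget,
        groups=groups,
        relevance=relevance,
        pseudo_labels=assign.labels,
        feature_groups=grouping,
    )
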