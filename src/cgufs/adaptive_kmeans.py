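"""Adaptive k-means: pseudo-labels with an automatically chosen cluster count.

k-means is scanned over candidate cluster counts k = 1..k1 and the sum of
squared errors J_k is recorded. The change function dJ_l = J_l - J_{l+1}
locates the elbow: the largest drop picks k when the curve decreases
monotonically, and the first *negative* drop (SSE rising as k grows) marks
that k has passed the true group count, in which case the point before the
rise is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .io import DataMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "ElbowTrace", "ElbowRule", "kmeans_fit", "compute_sse", "elbow_select", "adaptive_kmeans"]


class ElbowRule(str, Enum):
    MAX_DROP = "max_drop"
    NEGATIVE_ELBOW = "negative_elbow"
    DEGENERATE = "degenerate"


@dataclass
class ClusterAssignment:
    """Result of one k-means fit: labels in 0..k-1, centers, and SSE (J)."""

    labels: np.ndarray
    centers: np.ndarray
    k: int
    sse: float


@dataclass
class ElbowTrace:
    """SSE sequence over candidate k, its signed differences, and the choice."""

    j_values: np.ndarray
    deltas: np.ndarray
    chosen_k: int
    rule_used: ElbowRule


def compute_sse(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Sum of squared Euclidean distances of each point to its assigned center."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match number of rows")
    if labels.min() < 0 or labels.max() >= centers.shape[0]:
        raise IndexError("label outside the range of provided centers")
    diff = X - centers[labels]
    return float(np.sum(diff * diff))


def _canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by order of first occurrence in sample order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _lloyd(X: np.ndarray, init_centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centers = init_centers.copy()
    labels = np.full(n, -1, dtype=int)
    prev_sse = np.inf
    for _ in range(max_iter):
        dist = cdist(X, centers, metric="sqeuclidean")
        new_labels = np.argmin(dist, axis=1)
        # re-seed empty clusters at the sample farthest from the lost center;
        # stealing a sample can empty another cluster, so sweep until stable
        reseeded = False
        empty = [c for c in range(centers.shape[0]) if not np.any(new_labels == c)]
        while empty:
            for c in empty:
                far = int(np.argmax(dist[:, c]))
                # avoid samples that are their cluster's only member
                counts = np.bincount(new_labels, minlength=centers.shape[0])
                order = np.argsort(dist[:, c])[::-1]
                for cand in order:
                    if counts[new_labels[cand]] > 1:
                        far = int(cand)
                        break
                centers[c] = X[far]
                new_labels[far] = c
                reseeded = True
            empty = [c for c in range(centers.shape[0]) if not np.any(new_labels == c)]
        for c in range(centers.shape[0]):
            centers[c] = X[new_labels == c].mean(axis=0)
        sse = compute_sse(X, new_labels, centers)
        # Lloyd steps cannot increase J (re-seeding an empty cluster may)
        assert reseeded or sse <= prev_sse * (1 + 1e-9) + 1e-12, "SSE increased during Lloyd iteration"
        if np.array_equal(new_labels, labels):
            break
        labels, prev_sse = new_labels, sse
    return labels, centers, compute_sse(X, labels, centers)


def kmeans_fit(
    X: DataMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    restarts: int = 10,
) -> ClusterAssignment:
    """Best-of-``restarts`` Lloyd k-means with distinct-sample initialization.

    Each restart draws k distinct samples uniformly as initial centers;
    the run with the lowest SSE wins. Labels are relabelled canonically by
    first occurrence so the result is deterministic given the seed.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n = values.shape[0]
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    if k == 1:
        center = values.mean(axis=0, keepdims=True)
        labels = np.zeros(n, dtype=int)
        return ClusterAssignment(labels=labels, centers=center, k=1, sse=compute_sse(values, labels, center))

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        idx = rng.choice(n, size=k, replace=False)
        labels, centers, sse = _lloyd(values, values[idx], max_iter)
        if best is None or sse < best[2]:
            best = (labels, centers, sse)
    labels, centers, sse = best
    labels = _canonical_relabel(labels)
    # reorder centers to match the canonical labels
    order_centers = np.empty_like(centers)
    for c in range(k):
        order_centers[c] = values[labels == c].mean(axis=0)
    return ClusterAssignment(labels=labels, centers=order_centers, k=k, sse=compute_sse(values, labels, order_centers))


def elbow_select(j_values: np.ndarray, tol: float = 1e-9) -> tuple[int, ElbowRule]:
    """Choose k from an SSE trace J_1..J_k1 via the change function.

    A near-zero J_1 means the data are (numerically) a single point: k=1.
    Otherwise the first negative drop dJ_l < 0 (SSE rising) selects k = l,
    the point before the rise; with no rise, k is the right endpoint of the
    largest drop.
    """
    j = np.asarray(j_values, dtype=float)
    if j.size < 2:
        raise ValueError("need at least two SSE values")
    deltas = j[:-1] - j[1:]
    if j[0] <= tol:
        return 1, ElbowRule.DEGENERATE
    threshold = -tol * max(j[0], 1.0)
    negative = np.nonzero(deltas < threshold)[0]
    if negative.size:
        return int(negative[0]) + 1, ElbowRule.NEGATIVE_ELBOW
    return int(np.argmax(deltas)) + 2, ElbowRule.MAX_DROP


def adaptive_kmeans(
    X: DataMatrix | np.ndarray,
    k1: int = 10,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> tuple[ClusterAssignment, ElbowTrace]:
    """Scan k = 1..k1, record J_k, and return the assignment at the elbow.

    Assignments are cached per candidate k, so the returned clustering is
    exactly the one whose SSE entered the trace. k1 greater than n is
    clipped to n with a warning.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    n = values.shape[0]
    if k1 < 2:
        raise ValueError(f"k1 must be at least 2, got {k1}")
    if k1 > n:
        logger.warning("k1=%d exceeds n=%d; clipping to n", k1, n)
        k1 = n
    fits = [kmeans_fit(values, k, seed=seed + k, max_iter=max_iter, restarts=restarts) for k in range(1, k1 + 1)]
    j_values = np.array([f.sse for f in fits])
    chosen_k, rule = elbow_select(j_values, tol=tol)
    trace = ElbowTrace(j_values=j_values, deltas=j_values[:-1] - j_values[1:], chosen_k=chosen_k, rule_used=rule)
    logger.info("adaptive_kmeans: chose k=%d by %s", chosen_k, rule.value)
    return fits[chosen_k - 1], trace
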