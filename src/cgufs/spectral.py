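"""Spectral grouping of features.

Features (columns) are treated as points in sample space and connected by a
Gaussian similarity graph w_ij = exp(-||f_i - f_j||^2 / sigma^2). The rows of
the row-normalized eigenvector matrix of the normalized affinity
L = D^{-1/2} W D^{-1/2} embed the features (Ng-Jordan-Weiss convention:
the m largest eigenvalues of L, equivalently the m smallest of I - L), and
adaptive k-means on the embedding yields the feature groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .adaptive_kmeans import elbow_select, kmeans_fit
from .io import DataMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSimilarityGraph",
    "SpectralEmbedding",
    "FeatureGrouping",
    "DegenerateGraphError",
    "feature_similarity",
    "normalized_affinity",
    "spectral_embed",
    "group_features",
]


class DegenerateGraphError(ValueError):
    """All features are identical: the similarity graph carries no structure."""


@dataclass
class FeatureSimilarityGraph:
    W: np.ndarray  # symmetric, w_ii = 1, entries in (0, 1]
    sigma: float
    D: np.ndarray  # degree vector, D_i = sum_j W_ij
    L: np.ndarray  # normalized affinity D^{-1/2} W D^{-1/2}


@dataclass
class SpectralEmbedding:
    V: np.ndarray  # d x m eigenvectors, columns by descending eigenvalue
    Y: np.ndarray  # V with rows scaled to unit norm
    m: int
    eigenvalues: np.ndarray


@dataclass
class FeatureGrouping:
    """Group label per feature (0..u2-1); every group non-empty."""

    group_labels: np.ndarray
    u2: int


def feature_similarity(X: DataMatrix | np.ndarray, sigma: float | str = "auto") -> FeatureSimilarityGraph:
    """Gaussian similarity graph over features.

    With ``sigma="auto"`` the scale is the median pairwise Euclidean distance
    between features (falling back to the smallest positive distance when the
    median is zero). Raises :class:`DegenerateGraphError` when every pairwise
    distance is zero.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least two features")
    feats = values.T  # each feature is a point in n-dimensional sample space
    dist = pdist(feats, metric="euclidean")
    if sigma == "auto":
        med = float(np.median(dist))
        if med > 0:
            sig = med
        else:
            positive = dist[dist > 0]
            if positive.size == 0:
                raise DegenerateGraphError(
                    "all features identical; emit a trivial single-group result"
                )
            sig = float(positive.min())
            logger.warning("feature_similarity: median distance 0, using smallest positive %g", sig)
    else:
        sig = float(sigma)
        if sig <= 0:
            raise ValueError(f"sigma must be positive, got {sig}")
        if not np.any(dist > 0):
            raise DegenerateGraphError("all features identical; emit a trivial single-group result")
    W = np.exp(-squareform(dist) ** 2 / sig**2)
    np.fill_diagonal(W, 1.0)
    D = W.sum(axis=1)
    L = normalized_affinity(W)
    return FeatureSimilarityGraph(W=W, sigma=sig, D=D, L=L)


def normalized_affinity(W: np.ndarray) -> np.ndarray:
    """L = D^{-1/2} W D^{-1/2}; all eigenvalues lie in [-1, 1]."""
    W = np.asarray(W, dtype=float)
    D = W.sum(axis=1)
    if np.any(D <= 0):
        raise ValueError("zero row sum in similarity matrix")
    inv_sqrt = 1.0 / np.sqrt(D)
    L = W * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (L + L.T) / 2.0  # enforce exact symmetry


def spectral_embed(L: np.ndarray, m: int) -> SpectralEmbedding:
    """Eigenvectors for the m largest eigenvalues of L, rows scaled to unit norm.

    Eigenvector signs are fixed by making each column's largest-magnitude
    entry positive; all-zero rows of Y are left as zeros (and logged).
    """
    L = np.asarray(L, dtype=float)
    d = L.shape[0]
    if not 1 <= m <= d:
        raise ValueError(f"m must be in 1..{d}, got {m}")
    eigvals, eigvecs = eigh(L)
    order = np.argsort(eigvals)[::-1][:m]
    vals = eigvals[order]
    V = eigvecs[:, order]
    for col in range(m):
        pivot = np.argmax(np.abs(V[:, col]))
        if V[pivot, col] < 0:
            V[:, col] = -V[:, col]
    norms = np.linalg.norm(V, axis=1)
    zero_rows = norms <= 0
    if np.any(zero_rows):
        logger.warning("spectral_embed: %d all-zero embedding row(s) left unnormalized", int(zero_rows.sum()))
    Y = np.where(zero_rows[:, None], 0.0, V / np.where(zero_rows, 1.0, norms)[:, None])
    return SpectralEmbedding(V=V, Y=Y, m=m, eigenvalues=vals)


def group_features(
    X: DataMatrix | np.ndarray,
    k2: int = 10,
    seed: int = 0,
    sigma: float | str = "auto",
    restarts: int = 10,
) -> FeatureGrouping:
    """Spectral embedding of the feature graph followed by adaptive k-means.

    Every candidate group count u2 = 1..k2 is fitted in its own embedding of
    dimension max(u2, 2) (a one-dimensional row-normalized embedding of a
    connected graph collapses to a single point, so two dimensions is the
    floor). Once u2 exceeds the true block count the extra eigenvectors carry
    only noise and the k-means SSE rises, which the negative-elbow rule
    detects; the elbow over the SSE trace chooses u2 <= k2. A degenerate
    graph (all features identical) collapses to a single group with a
    warning.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    d = values.shape[1]
    if not 2 <= k2 <= d:
        raise ValueError(f"k2 must be in 2..{d}, got {k2}")
    try:
        graph = feature_similarity(values, sigma=sigma)
    except DegenerateGraphError:
        logger.warning("group_features: degenerate feature graph; single group")
        return FeatureGrouping(group_labels=np.zeros(d, dtype=int), u2=1)
    fits = []
    for u2 in range(1, k2 + 1):
        emb = spectral_embed(graph.L, m=min(max(u2, 2), d))
        fits.append(kmeans_fit(emb.Y, u2, seed=seed + u2, restarts=restarts))
    j_values = np.array([f.sse for f in fits])
    chosen_k, rule = elbow_select(j_values)
    logger.info("group_features: %d feature group(s) by %s", chosen_k, rule.value)
    return FeatureGrouping(group_labels=fits[chosen_k - 1].labels, u2=chosen_k)
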