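"""Discretization, entropy, information gain and symmetric uncertainty.

Continuous features are discretized once by equal-frequency binning; the
resulting integer codes serve both the feature-pseudo-label and the
feature-feature comparisons. All information quantities are plug-in
estimates in bits (base-2 logarithm). Symmetric uncertainty normalizes
mutual information into [0, 1]:

    SU(f, c) = 2 IG(f, c) / (H(f) + H(c))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizedVector",
    "RelevanceTable",
    "discretize",
    "entropy",
    "info_gain",
    "symmetric_uncertainty",
    "build_relevance_table",
]


@dataclass
class DiscretizedVector:
    """Integer codes 0..B-1 (contiguous, order-preserving) plus bin edges."""

    codes: np.ndarray
    bin_edges: np.ndarray
    B: int


@dataclass
class RelevanceTable:
    """Per-feature information quantities against the pseudo-labels.

    ``pairwise_ig`` caches IG between two features, filled lazily and only
    for pairs inside the same feature group.
    """

    su_cluster: np.ndarray
    ig_cluster: np.ndarray
    entropy_f: np.ndarray
    entropy_cluster: float
    codes: np.ndarray  # n x d discretized feature codes
    cluster_codes: np.ndarray
    pairwise_ig: dict[tuple[int, int], float] = field(default_factory=dict)

    def feature_pair_ig(self, p: int, q: int) -> float:
        key = (min(p, q), max(p, q))
        if key not in self.pairwise_ig:
            self.pairwise_ig[key] = info_gain(self.codes[:, p], self.codes[:, q])
        return self.pairwise_ig[key]


def discretize(values: np.ndarray, B: int = 5) -> DiscretizedVector:
    """Equal-frequency binning into at most B bins.

    Bin edges sit at the i/B quantiles; duplicate edges collapse, so heavily
    tied data occupy fewer bins. Codes are a contiguous, monotone relabelling.
    """
    values = np.asarray(values, dtype=float)
    if B < 1:
        raise ValueError(f"B must be at least 1, got {B}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if B == 1 or np.all(values == values[0]):
        return DiscretizedVector(codes=np.zeros(values.size, dtype=int), bin_edges=np.empty(0), B=1)
    edges = np.unique(np.quantile(values, np.arange(1, B) / B))
    raw = np.searchsorted(edges, values, side="left")
    _, codes = np.unique(raw, return_inverse=True)
    return DiscretizedVector(codes=codes.astype(int), bin_edges=edges, B=int(codes.max()) + 1)


def entropy(codes: np.ndarray) -> float:
    """Shannon entropy in bits of the empirical distribution of ``codes``."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty input")
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    return float(-(p * np.log2(p)).sum())


def info_gain(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information IG(a, b) = H(a) + H(b) - H(a, b), clipped at 0."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    joint = a.astype(np.int64) * (int(b.max()) + 1) + b.astype(np.int64)
    return max(0.0, entropy(a) + entropy(b) - entropy(joint))


def symmetric_uncertainty(f: np.ndarray, c: np.ndarray) -> float:
    """SU = 2 IG / (H(f) + H(c)); 0 when both vectors are constant."""
    f = np.asarray(f)
    c = np.asarray(c)
    if f.shape != c.shape:
        raise ValueError("vectors must have equal length")
    denom = entropy(f) + entropy(c)
    if denom == 0:
        return 0.0
    return min(1.0, 2.0 * info_gain(f, c) / denom)


def build_relevance_table(values: np.ndarray, pseudo_labels: np.ndarray, bins: int = 5) -> RelevanceTable:
    """Discretize every feature column and score it against the pseudo-labels."""
    values = np.asarray(values, dtype=float)
    pseudo = np.asarray(pseudo_labels).astype(int)
    n, d = values.shape
    if pseudo.size != n:
        raise ValueError("pseudo-label length must match the number of samples")
    codes = np.empty((n, d), dtype=int)
    for j in range(d):
        codes[:, j] = discretize(values[:, j], B=bins).codes
    h_cluster = entropy(pseudo)
    entropy_f = np.array([entropy(codes[:, j]) for j in range(d)])
    ig_cluster = np.array([info_gain(codes[:, j], pseudo) for j in range(d)])
    su_cluster = np.array([symmetric_uncertainty(codes[:, j], pseudo) for j in range(d)])
    return RelevanceTable(
        su_cluster=su_cluster,
        ig_cluster=ig_cluster,
        entropy_f=entropy_f,
        entropy_cluster=h_cluster,
        codes=codes,
        cluster_codes=pseudo,
    )
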