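"""Synthetic expression-like matrices with known structure.

The generator emulates the regime the method targets: a modest number of
samples falling into c well-separated clusters, g informative feature blocks
(one cluster-informative prototype plus additive-noise copies, so within a
block features are highly correlated), and a majority of pure-noise features
carrying no cluster signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io import DataMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "make_synthetic", "make_sample_blobs"]


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults are the standard benchmark.

    ``cluster_sep`` is the spacing of consecutive cluster means in units of
    the within-cluster standard deviation (which is 1); ``copy_noise_sd`` is
    the standard deviation of the additive noise on each redundant copy.
    """

    n: int = 120
    c: int = 3
    g: int = 5
    copies: int = 4
    d_noise: int = 75
    cluster_sep: float = 6.0
    copy_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2 or self.n < self.c:
            raise ValueError("need n >= c >= 2")
        if self.g < 1 or self.copies < 0 or self.d_noise < 0:
            raise ValueError("g >= 1, copies >= 0, d_noise >= 0 required")
        if self.cluster_sep <= 0:
            raise ValueError("cluster_sep must be positive")

    @property
    def d(self) -> int:
        return self.g * (1 + self.copies) + self.d_noise


@dataclass
class SyntheticTruth:
    sample_labels: np.ndarray  # length n
    feature_block: np.ndarray  # length d; block id, -1 for noise features
    prototype_indices: list[int]


def make_synthetic(spec: SyntheticSpec) -> tuple[DataMatrix, SyntheticTruth]:
    """Generate the matrix plus ground truth; deterministic given the seed.

    Samples are assigned to clusters round-robin (balanced to within 1).
    Each block's prototype takes cluster-dependent means spaced cluster_sep
    apart, but blocks respond to the clusters in distinct orders (block b
    uses the b-th permutation of the spaced means, as distinct gene modules
    are up- or down-regulated in different cluster patterns); copies add
    N(0, copy_noise_sd) on top of the prototype; noise features are standard
    normal. The permuted patterns keep blocks mutually distinguishable --
    and only partially mutually informative -- while every block stays
    informative about the sample clusters.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n) % spec.c
    d = spec.d
    values = np.empty((spec.n, d))
    feature_block = np.full(d, -1, dtype=int)
    prototype_indices: list[int] = []

    perms = list(itertools.permutations(range(spec.c)))
    col = 0
    for b in range(spec.g):
        order = np.array(perms[b % len(perms)], dtype=float)
        means = order * spec.cluster_sep
        prototype = means[labels] + rng.standard_normal(spec.n)
        prototype_indices.append(col)
        feature_block[col] = b
        values[:, col] = prototype
        col += 1
        for _ in range(spec.copies):
            feature_block[col] = b
            values[:, col] = prototype + spec.copy_noise_sd * rng.standard_normal(spec.n)
            col += 1
    if spec.d_noise:
        values[:, col:] = rng.standard_normal((spec.n, spec.d_noise))

    X = DataMatrix(values=values)
    truth = SyntheticTruth(
        sample_labels=labels,
        feature_block=feature_block,
        prototype_indices=prototype_indices,
    )
    return X, truth


def make_sample_blobs(
    n: int, c: int, sep: float, dim: int = 2, seed: int = 0
) -> tuple[DataMatrix, np.ndarray]:
    """Isotropic unit-variance Gaussian blobs with centers ``sep`` apart.

    Cluster centers sit at sep times distinct unit directions (standard
    basis vectors when c <= dim, otherwise random unit vectors); labels are
    balanced round-robin. ``sep=0`` collapses to a single cloud.
    """
    if n < c or c < 1:
        raise ValueError("need n >= c >= 1")
    if sep < 0:
        raise ValueError("sep must be nonnegative")
    rng = np.random.default_rng(seed)
    if c <= dim:
        directions = np.eye(dim)[:c]
    else:
        directions = rng.standard_normal((c, dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    labels = np.arange(n) % c
    values = sep * directions[labels] + rng.standard_normal((n, dim))
    return DataMatrix(values=values), labels
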