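"""Shared fixtures: small matrices and correlated feature-block data."""

from __future__ import annotations

import numpy as np
import pytest

from cgufs import DataMatrix


def make_feature_blocks(
    n: int = 60,
    g: int = 3,
    per_block: int = 10,
    copy_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature blocks of one N(0,1) prototype plus near-copies.

    Prototypes are independent, so within-block correlation is ~1 and
    between-block correlation is ~0 by construction.
    """
    rng = np.random.default_rng(seed)
    cols, blocks = [], []
    for b in range(g):
        proto = rng.standard_normal(n)
        cols.append(proto)
        blocks.append(b)
        for _ in range(per_block - 1):
            cols.append(proto + copy_sd * rng.standard_normal(n))
            blocks.append(b)
    return np.array(cols).T, np.array(blocks)


@pytest.fixture
def small_matrix() -> DataMatrix:
    rng = np.random.default_rng(11)
    return DataMatrix(values=rng.standard_normal((20, 10)))
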