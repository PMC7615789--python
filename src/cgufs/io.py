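"""Reading and writing expression matrices and selection results.

Matrices are delimited text with samples as rows and features as columns.
An optional header row carries feature identifiers and an optional first
column carries sample identifiers; missing identifiers are synthesized as
``S1..Sn`` / ``F1..Fd``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DataMatrix", "MatrixParseError", "read_matrix", "write_matrix", "standardize", "write_selection"]


class MatrixParseError(ValueError):
    """Raised when a delimited matrix file cannot be parsed."""


@dataclass
class DataMatrix:
    """An n x d numeric matrix: rows are samples, columns are features.

    All entries must be finite and identifier lists unique; both dimensions
    must be at least 2.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise ValueError(f"matrix must be at least 2 x 2, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite entry at row {bad[0]}, column {bad[1]}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"F{j + 1}" for j in range(d)]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.feature_ids)) != d:
            raise ValueError("feature ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, indices: Sequence[int]) -> "DataMatrix":
        """Restrict to the given feature columns, preserving sample order."""
        idx = list(indices)
        return DataMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in idx],
        )


def read_matrix(
    path: str | Path,
    has_header: bool = True,
    has_row_ids: bool = True,
    delimiter: str = ",",
) -> DataMatrix:
    """Load a samples x features matrix from delimited text.

    Raises :class:`MatrixParseError` with the offending row/column on ragged
    rows or non-numeric cells, and ``ValueError`` if the matrix is smaller
    than 2 x 2 or contains non-finite values.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")

    feature_ids: list[str] = []
    if has_header:
        header = lines.pop(0).split(delimiter)
        feature_ids = [h.strip() for h in (header[1:] if has_row_ids else header)]

    sample_ids: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    for i, line in enumerate(lines):
        cells = line.split(delimiter)
        if has_row_ids:
            sample_ids.append(cells[0].strip())
            cells = cells[1:]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise MatrixParseError(
                f"{path}: ragged row at line {i + 1 + int(has_header)} "
                f"({len(cells)} fields, expected {width})"
            )
        row = []
        for j, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell {cell.strip()!r} at row {i + 1}, column {j + 1}"
                ) from None
        rows.append(row)

    values = np.asarray(rows, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(f"{path}: matrix must be at least 2 x 2, got shape {values.shape}")
    return DataMatrix(values=values, sample_ids=sample_ids, feature_ids=feature_ids if has_header else [])


def write_matrix(X: DataMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a matrix with a feature-id header and sample-id first column."""
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def standardize(X: DataMatrix) -> DataMatrix:
    """Center each feature to mean 0 and scale non-constant features to unit sd.

    Constant columns become all-zero. Idempotent up to floating-point noise.
    """
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    centered = X.values - mu
    nonconstant = sd > 0
    out = np.where(nonconstant, centered / np.where(nonconstant, sd, 1.0), 0.0)
    n_const = int((~nonconstant).sum())
    if n_const:
        logger.warning("standardize: %d constant feature(s) set to all-zero", n_const)
    return DataMatrix(values=out, sample_ids=list(X.sample_ids), feature_ids=list(X.feature_ids))


def write_selection(result, X: DataMatrix, path: str | Path, reduced_path: str | Path | None = None) -> None:
    """Write retained features and per-group metadata; optionally the reduced matrix.

    The report has one row per retained feature: feature id, 0-based column
    index, its feature-group id, its role (main/effective) and its symmetric
    uncertainty with the pseudo-labels. An empty retained set yields a
    header-only file.
    """
    retained = list(result.retained_indices)
    if any(j >= X.n_features for j in retained):
        raise IndexError("retained index out of range")
    role = {}
    group_of = {}
    for g in result.groups:
        group_of.update({j: g.group_id for j in g.member_indices})
        role[g.main_index] = "main"
        role.update({j: "effective" for j in g.effective_indices})
        role.update({j: "redundant" for j in g.redundant_indices})
    rows = [
        {
            "feature_id": X.feature_ids[j],
            "index": j,
            "group": group_of.get(j, -1),
            "role": role.get(j, "unknown"),
            "su_cluster": result.relevance.su_cluster[j],
        }
        for j in retained
    ]
    pd.DataFrame(rows, columns=["feature_id", "index", "group", "role", "su_cluster"]).to_csv(path, index=False)
    if reduced_path is not None:
        write_matrix(X.subset_features(retained), reduced_path)
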