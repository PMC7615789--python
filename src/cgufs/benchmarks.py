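"""Published benchmark summaries used as worked examples.

These are the reported per-dataset results of CGUFS and seven comparator
unsupervised feature-selection algorithms on standard high-dimensional
benchmark datasets, evaluated through C4.5 and Adaboost classifiers. They
feed the aggregation and ranking utilities as worked examples; the external
datasets themselves are not required.

ACC/MCC values are percentages; FS is the retained-feature count at each
algorithm's optimal operating point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DATASETS",
    "ALGORITHMS",
    "c45_acc_table",
    "cgufs_columns",
    "cgufs_average",
    "abstract_headline",
]

DATASETS = ["ALLAML", "GLIOMA", "warpAR10P", "warpPIE10P", "Colon", "Yale", "Madelon"]

ALGORITHMS = ["Laplacian", "MCFS", "UDFS", "FSASL", "SCUFS", "IUFS", "DGUFS", "CGUFS"]

# C4.5 accuracy (%) at each algorithm's optimal feature count, per dataset.
_C45_ACC = {
    "Laplacian": [66.7, 54.0, 46.2, 76.7, 77.4, 43.6, 80.8],
    "MCFS": [77.8, 58.0, 53.9, 81.0, 85.5, 50.9, 73.2],
    "UDFS": [84.7, 54.0, 53.9, 80.5, 79.0, 45.5, 72.5],
    "FSASL": [80.6, 56.0, 66.2, 84.8, 85.5, 53.3, 67.9],
    "SCUFS": [81.9, 64.0, 43.1, 47.6, 75.8, 45.5, 80.8],
    "IUFS": [76.4, 80.0, 60.0, 84.3, 83.9, 49.7, 74.9],
    "DGUFS": [79.2, 62.0, 54.6, 79.5, 67.7, 47.3, 57.7],
    "CGUFS": [84.7, 66.0, 67.7, 79.1, 87.1, 55.2, 80.8],
}

# Per-dataset CGUFS columns of the remaining report tables.
_CGUFS = {
    "c45_acc": [84.7, 66.0, 67.7, 79.1, 87.1, 55.2, 80.8],
    "c45_mcc": [66.6, 53.7, 64.3, 76.9, 71.8, 52.0, 61.6],
    "ada_acc": [90.3, 68.0, 94.8, 79.2, 88.7, 65.5, 85.8],
    "ada_mcc": [78.4, 57.9, 77.3, 94.2, 75.3, 63.1, 71.6],
    "c45_fs": [60, 10, 130, 100, 150, 60, 10],
}


def c45_acc_table() -> pd.DataFrame:
    """Datasets x algorithms grid of C4.5 accuracies (%) at the optimum."""
    return pd.DataFrame(_C45_ACC, index=DATASETS, columns=ALGORITHMS, dtype=float)


def cgufs_columns() -> pd.DataFrame:
    """Per-dataset CGUFS results: C4.5/Adaboost ACC and MCC (%), C4.5 FS."""
    return pd.DataFrame(_CGUFS, index=DATASETS)


def cgufs_average(metric: str) -> float:
    """Across-dataset mean of a CGUFS column, rounded to the reported 2 dp."""
    col = cgufs_columns()[metric]
    return round(float(np.mean(col)), 2)


def abstract_headline() -> tuple[float, float]:
    """The headline (C4.5 mean ACC, C4.5 mean MCC) pair, as percentages."""
    return cgufs_average("c45_acc"), cgufs_average("c45_mcc")
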