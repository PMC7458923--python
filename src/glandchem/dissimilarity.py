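"""Bray-Curtis dissimilarity.

d(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i), bounded in [0, 1]; for rows
closed to 100 percent this reduces to sum|x_i - y_i| / 200.  Bray-Curtis is a
semi-metric (the triangle inequality can fail), so downstream principal
coordinates must tolerate negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .profile_io import CompoundTable, ProfileError


@dataclass
class DissimilarityMatrix:
    """Dense symmetric dissimilarity matrix in source-table sample order."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ProfileError("dissimilarity matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ProfileError("dissimilarity matrix not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ProfileError("dissimilarity matrix diagonal not zero")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ProfileError("dissimilarity entries outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.sample_ids, name="sample_id")
        return pd.DataFrame(self.values, index=idx, columns=self.sample_ids)


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ProfileError("profiles differ in length")
    denom = float((x + y).sum())
    if denom <= 0:
        raise ProfileError("both profiles all-zero: Bray-Curtis undefined")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: CompoundTable) -> DissimilarityMatrix:
    if table.n_samples < 2:
        raise ProfileError("need at least 2 samples")
    X = table.abundances
    sums = X.sum(axis=1)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ProfileError(
            f"all-zero row for sample {table.sample_ids[zero[0]]!r}"
        )
    num = cdist(X, X, metric="cityblock")
    den = sums[:, None] + sums[None, :]
    values = num / den
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return DissimilarityMatrix(list(table.sample_ids), values)


def write_matrix(d: DissimilarityMatrix, path: Union[str, Path]) -> None:
    d.to_frame().to_csv(path, float_format="%.17g")


def read_matrix(path: Union[str, Path]) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return DissimilarityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
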