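"""Seed-level time series → correlation matrices → canonical FC vectors.

A participant-stage scan is summarized as the Pearson correlation matrix
of its seed time series; since the matrix is symmetric with unit
diagonal, only the C(S, 2) unique off-diagonal coefficients are kept.
The vector index convention is fixed package-wide: row-lexicographic
over pairs (i, j) with i < j, 0-based (the order of
``numpy.triu_indices(s, 1)``), so index ``k`` is self-describing given
the seed count ``s``.  For the 236-seed template this yields the
familiar 27,730-dimensional FC vector out of 55,696 matrix entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityRecord",
    "n_unique_pairs",
    "correlation_matrix",
    "vectorize_unique",
    "devectorize",
    "index_to_pair",
    "pair_to_index",
    "fisher_z",
    "inverse_fisher_z",
    "read_series_tsv",
    "write_series_tsv",
]

_SYMMETRY_TOL = 1e-8


def n_unique_pairs(s: int) -> int:
    """C(s, 2): length of the FC vector for ``s`` seeds."""
    return s * (s - 1) // 2


@dataclass
class ConnectivityRecord:
    """One participant-stage FC vector with its indexing metadata."""

    participant_id: str
    stage: str  # "pre" | "post"
    values: np.ndarray
    s: int

    def __post_init__(self) -> None:
        if self.stage not in ("pre", "post"):
            raise ValueError(f"stage must be 'pre' or 'post', got {self.stage!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n_unique_pairs(self.s),):
            raise ValueError(
                f"FC vector length {self.values.size} != C({self.s},2) = {n_unique_pairs(self.s)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FC vector contains non-finite values")
        if np.any(np.abs(self.values) > 1):
            raise ValueError("correlations must lie in [-1, 1]")


def correlation_matrix(series: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pearson correlation matrix (S×S) of a T×S time-series table.

    Constant columns are an error (a silently-NaN feature would corrupt
    the downstream outlier screen), reported by seed index.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a 2-D T×S table")
    t, s = x.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant time series (zero temporal variance) at seed(s) {constant.tolist()}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def vectorize_unique(matrix: np.ndarray) -> np.ndarray:
    """Unique off-diagonal entries in (i<j) lexicographic order."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=_SYMMETRY_TOL, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju].copy()


def devectorize(values: np.ndarray, s: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_unique` (off-diagonal part)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (n_unique_pairs(s),):
        raise ValueError(f"expected C({s},2) = {n_unique_pairs(s)} values, got {values.size}")
    m = np.full((s, s), diagonal, dtype=float)
    iu, ju = np.triu_indices(s, k=1)
    m[iu, ju] = values
    m[ju, iu] = values
    return m


def index_to_pair(k: int | np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Map FC vector indices to 0-based seed pairs (i, j), i < j.

    Vectorized; scalar input returns a pair of Python ints.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    total = n_unique_pairs(s)
    if np.any((k_arr < 0) | (k_arr >= total)):
        raise IndexError(f"index out of range 0..{total - 1}")
    # offsets[i] = index of pair (i, i+1); search for the owning row.
    rows = np.arange(s - 1, dtype=np.int64)
    offsets = rows * s - rows * (rows + 1) // 2
    i = np.searchsorted(offsets, k_arr, side="right") - 1
    j = k_arr - offsets[i] + i + 1
    if np.isscalar(k) or np.asarray(k).ndim == 0:
        return int(i[0]), int(j[0])
    return i, j


def pair_to_index(i: int | np.ndarray, j: int | np.ndarray, s: int) -> int | np.ndarray:
    """Inverse of :func:`index_to_pair`."""
    i_arr = np.atleast_1d(np.asarray(i, dtype=np.int64))
    j_arr = np.atleast_1d(np.asarray(j, dtype=np.int64))
    if np.any((i_arr < 0) | (j_arr >= s) | (i_arr >= j_arr)):
        raise IndexError("require 0 <= i < j < s")
    k = i_arr * s - i_arr * (i_arr + 1) // 2 + (j_arr - i_arr - 1)
    if np.isscalar(i) and np.isscalar(j):
        return int(k[0])
    return k


def fisher_z(values: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Fisher z-transform (atanh), elementwise.

    Off by default in the pipeline (the SVM makes no normality
    assumption on its inputs); provided for completeness.  |r| = 1 is an
    error unless ``clamp`` nudges it inside the open interval.
    """
    v = np.asarray(values, dtype=float)
    if clamp:
        eps = np.finfo(float).eps
        v = np.clip(v, -1 + eps, 1 - eps)
    elif np.any(np.abs(v) >= 1):
        raise ValueError("Fisher z undefined at |r| = 1 (set clamp=True to clip)")
    return np.arctanh(v)


def inverse_fisher_z(values: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(values, dtype=float))


def read_series_tsv(path) -> np.ndarray:
    """Read a T×S series table (TSV, one column per seed)."""
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_series_tsv(series: np.ndarray, path) -> None:
    s = series.shape[1]
    pd.DataFrame(series, columns=[f"seed_{i:03d}" for i in range(s)]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
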