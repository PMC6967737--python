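"""Symmetric Laplace normalization of similarity matrices.

A similarity matrix S becomes the walk's transition matrix
T = Y^{-1/2} S Y^{-1/2}, where Y is the diagonal of row sums, i.e.
T(i,j) = S(i,j) / sqrt(r_i c_j) with r_i the i-th row sum and c_j the
j-th column sum, and T(i,j) = 0 whenever either sum vanishes.  For a
nonnegative symmetric S the spectrum of T lies within [-1, 1]; rows do
not generally sum to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["laplace_normalize"]

#: row/column sums below this are treated as exactly zero
ZERO_SUM_TOL = 1e-12
_SYMMETRY_TOL = 1e-8


def laplace_normalize(s: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Symmetrically degree-normalize a nonnegative symmetric matrix.

    Row and column sums are computed independently and checked against
    each other, so near-symmetric numerical input behaves predictably;
    input asymmetric beyond tolerance is an error.  Scale-invariant:
    normalizing c·S gives the same result for any c > 0.
    """
    is_frame = isinstance(s, pd.DataFrame)
    vals = s.to_numpy(dtype=float) if is_frame else np.asarray(s, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.any(vals < 0):
        raise ValueError("similarity matrix must be nonnegative")
    scale = max(np.abs(vals).max(), 1.0)
    if np.max(np.abs(vals - vals.T)) > _SYMMETRY_TOL * scale:
        raise ValueError("similarity matrix is asymmetric beyond tolerance")
    row_sums = vals.sum(axis=1)
    col_sums = vals.sum(axis=0)
    if np.max(np.abs(row_sums - col_sums)) > _SYMMETRY_TOL * max(row_sums.max(), 1.0):
        raise ValueError("row and column sums disagree beyond tolerance")
    r = np.where(row_sums < ZERO_SUM_TOL, 0.0, row_sums)
    c = np.where(col_sums < ZERO_SUM_TOL, 0.0, col_sums)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vals / np.sqrt(np.outer(r, c))
    out[~np.isfinite(out)] = 0.0
    out = (out + out.T) / 2.0
    if is_frame:
        return pd.DataFrame(out, index=s.index, columns=s.columns)
    return out
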