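"""Small shared helpers: the canonical pair ordering and symmetric-matrix
vectorization used by every stage that works with region-pair features.

The canonical order of the P = N(N-1)/2 unordered region pairs is the strict
lower triangle scanned row by row: (1,0), (2,0), (2,1), (3,0), ...
"""
from __future__ import annotations

import numpy as np

from .errors import SchemaError


def lower_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict lower triangle in canonical order."""
    return np.tril_indices(n, -1)


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def sym_to_vec(mat: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric matrix over the strict lower triangle."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise SchemaError(f"expected a square matrix, got shape {mat.shape}")
    i, j = lower_pairs(mat.shape[0])
    return mat[i, j]


def vec_to_sym(vec: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`sym_to_vec`; the diagonal is set to ``diag``."""
    vec = np.asarray(vec)
    if vec.shape[-1] != n_pairs(n):
        raise SchemaError(
            f"vector of length {vec.shape[-1]} does not match n={n} "
            f"(expected {n_pairs(n)})"
        )
    out = np.full((n, n), diag, dtype=float)
    i, j = lower_pairs(n)
    out[i, j] = vec
    out[j, i] = vec
    return out


def zscore_columns(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column-wise z-scoring; raises on zero-variance columns."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        from .errors import DegenerateSeriesError

        raise DegenerateSeriesError(f"zero-variance columns: {bad.tolist()}")
    return (x - x.mean(axis=0)) / sd
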