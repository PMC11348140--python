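"""Group-difference mapping and summary statistics for interaction matrices.

Implements the case-control comparison stage: per-pair two-sample t-tests
with confound residualization (age, gender, motion, site by default),
regional and network summaries of the resulting t-map, whole-brain mean
scores, Benjamini-Hochberg control, and the paired/variance comparisons
used to contrast interaction kinds.

Confounds are regressed out of each pair's values across subjects first
(ordinary least squares with dummy-coded categoricals), then the
two-sample t statistic is computed on the residuals with pooled variance.
Degrees of freedom are not adjusted for the residualization step; this
two-stage procedure is a documented simplification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    CollinearityError,
    InsufficientSampleError,
    InvalidArgumentError,
    SchemaError,
)
from .infodynamics import InteractionMatrix
from .util import lower_pairs, sym_to_vec, vec_to_sym


@dataclass
class GroupDiffMap:
    """Pairwise between-group t statistics, contrast NC - SCZ."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    contrast: str = "NC-SCZ"
    kind: str = "synergy"


def design_matrix(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list]:
    """Intercept-plus-covariates design with dummy-coded categoricals."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["intercept"]
    cov = covariates.reset_index(drop=True)
    numeric = cov.select_dtypes(include=[np.number])
    categorical = cov.select_dtypes(exclude=[np.number])
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for c in numeric.columns:
        cols.append(numeric[c].to_numpy(float))
        names.append(c)
    if categorical.shape[1]:
        dummies = pd.get_dummies(categorical, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for k in range(1, X.shape[1]):
            sub = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[k])
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]})",
            columns=bad,
        )
    return X, names


def residualize(y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of y (vector or subjects x features) on the covariates."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X, _ = design_matrix(covariates, n)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled-variance two-sample t over columns; contrast mean(a) - mean(b)."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(p, np.finfo(float).tiny, 1.0), df


def group_t_map(
    matrices: list[InteractionMatrix],
    groups: list[str] | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> GroupDiffMap:
    """Per-pair two-sample t map (NC - SCZ) on residualized entries."""
    groups = np.asarray(groups)
    if len(matrices) != len(groups):
        raise SchemaError("matrices and groups must have equal length")
    n_nc = int(np.sum(groups == "NC"))
    n_scz = int(np.sum(groups == "SCZ"))
    if n_nc < 3 or n_scz < 3:
        raise InsufficientSampleError("each group needs at least 3 subjects")
    n = matrices[0].values.shape[0]
    Y = np.stack([sym_to_vec(m.values) for m in matrices])  # (S, P)
    Y = residualize(Y, covariates)
    t, p, df = _two_sample_t(Y[groups == "NC"], Y[groups == "SCZ"])
    return GroupDiffMap(
        t_values=vec_to_sym(t, n),
        p_values=vec_to_sym(p, n, diag=1.0),
        df=df,
        kind=matrices[0].kind,
    )


def regional_profile(diff: GroupDiffMap | np.ndarray) -> np.ndarray:
    """Per-region mean of the t matrix row, excluding the diagonal."""
    mat = diff.t_values if isinstance(diff, GroupDiffMap) else np.asarray(diff)
    n = mat.shape[0]
    return (mat.sum(axis=1) - np.diag(mat)) / (n - 1)


def network_summary(
    values: np.ndarray, networks: list[str] | np.ndarray
) -> pd.DataFrame:
    """Per-network mean/sd of a regional vector, or block means of a matrix."""
    networks = np.asarray(networks)
    values = np.asarray(values, dtype=float)
    known = set(networks)
    if values.ndim == 1:
        if len(values) != len(networks):
            raise SchemaError("vector length does not match network labels")
        df = pd.DataFrame({"network": networks, "value": values})
        out = df.groupby("network", sort=False)["value"].agg(["mean", "std", "count"])
        return out.reset_index()
    if values.ndim == 2:
        if values.shape[0] != len(networks):
            raise SchemaError("matrix size does not match network labels")
        nets = list(dict.fromkeys(networks))
        rows = []
        for na in nets:
            for nb in nets:
                ia = np.flatnonzero(networks == na)
                ib = np.flatnonzero(networks == nb)
                block = values[np.ix_(ia, ib)]
                if na == nb:
                    mask = ~np.eye(len(ia), dtype=bool)
                    block = block[mask]
                rows.append(
                    {"network_a": na, "network_b": nb, "mean": float(np.mean(block))}
                )
        return pd.DataFrame(rows)
    raise SchemaError("values must be a vector or a square matrix")


def subject_mean_score(matrix: InteractionMatrix | np.ndarray) -> float:
    """Whole-brain mean over the strict lower triangle."""
    mat = matrix.values if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    return float(sym_to_vec(mat).mean())


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejections, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def paired_profile_test(profile_a, profile_b) -> tuple[float, float]:
    """Paired two-sided t-test across regions of two regional profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise SchemaError("profiles must have equal length")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        raise InvalidArgumentError(
            "paired differences have zero variance (constant nonzero shift)"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def variance_comparison(scores_a, scores_b) -> tuple[float, float]:
    """Compare dispersions via a two-sample t-test on squared deviations.

    Each sample is centered on its own mean; the t-test then compares the
    mean squared deviation between groups.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientSampleError("need at least 3 values per sample")
    da = (a - a.mean()) ** 2
    db = (b - b.mean()) ** 2
    t, p = stats.ttest_ind(da, db)
    return float(t), float(p)
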