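"""Imaging-transcriptomics stage: linking factor maps to gene expression.

Given a region x gene expression matrix and a regional factor map, this
module (1) correlates every gene's expression profile with the map,
(2) selects the top/bottom ranked genes as the factor's risk set,
(3) builds a regional co-expression matrix over risk genes (Spearman
correlations between region profiles, Fisher z-transformed), correlates
its regional strength with the factor map under a spatial-
autocorrelation-aware permutation test, and (4) scores every risk gene
by virtual knockout: the change in that co-expression/factor-map
correlation when the gene is removed (the gene contribution indicator,
GCI; GCI+ genes support the correlation, GCI- genes oppose it).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidArgumentError, SchemaError
from .spatialnull import sa_corr_test

ATANH_CAP = 1.0 - 1e-6


def gene_factor_correlations(expr: pd.DataFrame, fmap: np.ndarray) -> pd.Series:
    """Pearson r between each gene's regional expression and the factor map.

    Constant gene columns get r = 0 and are reported in the series'
    ``attrs['flagged']`` list.
    """
    X = expr.to_numpy(dtype=float)
    y = np.asarray(fmap, dtype=float)
    if X.shape[0] != len(y):
        raise SchemaError("expression and factor map region counts differ")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    flagged = np.flatnonzero(sx == 0)
    sx_safe = np.where(sx == 0, 1.0, sx)
    r = (Xc * yc[:, None]).mean(axis=0) / (sx_safe * sy)
    r[flagged] = 0.0
    out = pd.Series(r, index=expr.columns, name="r")
    out.attrs["flagged"] = [expr.columns[k] for k in flagged]
    return out


def select_risk_genes(
    rs: pd.Series, n_top: int = 1500, n_bottom: int = 1500
) -> tuple[list, list, list]:
    """Top/bottom ranked genes by correlation; ties broken by gene id.

    Returns (top set, bottom set, union).  The union preserves rank order
    (top first) and deduplicates.
    """
    if n_top + n_bottom > len(rs):
        raise InvalidArgumentError("n_top + n_bottom exceeds the gene count")
    df = pd.DataFrame({"r": rs.values, "gene": rs.index}).sort_values(
        ["r", "gene"], ascending=[False, True], kind="stable"
    )
    genes = df["gene"].tolist()
    top = genes[:n_top]
    bottom = genes[-n_bottom:][::-1] if n_bottom else []
    union = list(dict.fromkeys(top + bottom))
    return top, bottom, union


def coexpression_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Region x region Fisher-z Spearman co-expression over the gene set.

    Region profiles are ranked across genes; Pearson correlation of the
    ranks gives Spearman rho, which is atanh-transformed.  Perfectly
    correlated profiles (duplicated regions) are capped just below 1 so
    the transform stays finite; the diagonal is set to 0.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise InvalidArgumentError("need at least 3 genes")
    ranks = rankdata(X, axis=1)
    if np.any(ranks.std(axis=1) == 0):
        bad = np.flatnonzero(ranks.std(axis=1) == 0).tolist()
        raise InvalidArgumentError(f"regions with fully tied profiles: {bad}")
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -ATANH_CAP, ATANH_CAP)
    z = np.arctanh(rho)
    np.fill_diagonal(z, 0.0)
    return z


def coexpression_strength(coexp: np.ndarray) -> np.ndarray:
    """Regional co-expression strength: row mean excluding the diagonal."""
    n = coexp.shape[0]
    return (coexp.sum(axis=1) - np.diag(coexp)) / (n - 1)


def coexpression_factor_corr(
    coexp: np.ndarray,
    fmap: np.ndarray,
    distmat: np.ndarray | None = None,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between regional co-expression strength and a factor map.

    Returns (r, p_SA); p_SA is NaN when no distance matrix is supplied.
    """
    strength = coexpression_strength(coexp)
    y = np.asarray(fmap, dtype=float)
    if len(strength) != len(y):
        raise SchemaError("co-expression and factor map region counts differ")
    if distmat is None:
        return float(np.corrcoef(strength, y)[0, 1]), float("nan")
    return sa_corr_test(strength, y, distmat, n=n_surrogates, seed=seed)


def virtual_knockout(expr: pd.DataFrame, fmap: np.ndarray) -> pd.DataFrame:
    """Gene contribution indicators for every gene of a risk set.

    For each gene g the co-expression matrix is rebuilt without g and the
    strength/factor-map correlation recomputed; GCI_g = r_all - r_without_g.
    Positive GCI means the gene supports the gene-factor correlation.
    """
    if expr.shape[1] < 4:
        raise InvalidArgumentError("need at least 4 genes")
    y = np.asarray(fmap, dtype=float)
    r_all, _ = coexpression_factor_corr(coexpression_matrix(expr), y)
    rows = []
    for g in expr.columns:
        sub = expr.drop(columns=[g])
        r_g, _ = coexpression_factor_corr(coexpression_matrix(sub), y)
        gci = r_all - r_g
        rows.append(
            {
                "gene": g,
                "gci": gci,
                "sign_class": "GCI+" if gci > 0 else ("GCI-" if gci < 0 else "zero"),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
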