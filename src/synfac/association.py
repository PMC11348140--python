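"""Associations between factor expressions and subject characteristics.

Three complementary analyses:

* representational similarity analysis (RSA): subject-by-subject
  dissimilarity matrices (RDMs) for factor loadings, raw synergy
  z-scores, and each demographic/clinical characteristic, compared with
  Kendall tau-b over their lower triangles;
* per-site and pooled Pearson correlations between factor loadings and
  PANSS subscales, with non-clinical covariates regressed out of both
  sides and Fisher-z confidence intervals, FDR-controlled over the
  factor x scale family;
* a general linear model Y ~ 1 + p1 + p2 over the loading simplex (p3 is
  implicit because loadings sum to one), with general-linear-hypothesis
  contrasts H beta = 0 comparing pairs of factors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .cohortstats import fdr_bh, residualize
from .errors import (
    CollinearityError,
    InvalidArgumentError,
    MissingDataError,
    SchemaError,
    UndefinedCorrelationError,
)


@dataclass
class RDM:
    """Subject dissimilarity matrix for one characteristic."""

    label: str
    d: np.ndarray  # (S, S) symmetric, zero diagonal


def rdm(values, kind: str = "numeric", label: str = "") -> RDM:
    """Dissimilarity matrix: |xi - xj| (scalars), Euclidean distance
    (vectors), or 0/1 mismatch (categorical)."""
    if kind == "categorical":
        v = np.asarray(values, dtype=object)
        if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in v):
            bad = [k for k, x in enumerate(v) if x is None or (isinstance(x, float) and np.isnan(x))]
            raise MissingDataError("missing categorical values", subjects=bad)
        d = (v[:, None] != v[None, :]).astype(float)
    elif kind == "numeric":
        v = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[:, 0].tolist()
            raise MissingDataError("missing numeric values", subjects=sorted(set(bad)))
        if v.ndim == 1:
            v = v[:, None]
        d = squareform(pdist(v, metric="euclidean"))
    else:
        raise InvalidArgumentError(f"unknown RDM kind {kind!r}")
    np.fill_diagonal(d, 0.0)
    return RDM(label=label, d=d)


def kendall_tau_lower(rdm_a: RDM, rdm_b: RDM) -> float:
    """Kendall tau-b between the strict lower triangles of two RDMs."""
    da, db = rdm_a.d, rdm_b.d
    if da.shape != db.shape:
        raise SchemaError("RDMs must cover the same subjects")
    il = np.tril_indices(da.shape[0], -1)
    a, b = da[il], db[il]
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError("constant RDM triangle")
    tau, _ = stats.kendalltau(a, b, variant="b")
    return float(tau)


def rsa_compare(
    loading_runs: list[np.ndarray],
    raw_z: np.ndarray,
    characteristics: pd.DataFrame,
    categorical: tuple[str, ...] = ("gender", "site"),
    run_bounds: np.ndarray | None = None,
) -> pd.DataFrame:
    """RSA model-fit comparison: factor-expression RDMs versus raw-z RDM.

    For every characteristic, Kendall tau is computed between its RDM and
    (a) the loading RDM of each LDA run and (b) the single RDM of the raw
    vectorized z-scores.  A one-sample t-test locates the run
    distribution relative to the raw-z baseline.  The "final estimate"
    column reports the run with the highest training bound when
    ``run_bounds`` is given (otherwise the last run).
    """
    if len(loading_runs) < 2:
        raise InvalidArgumentError("need at least two runs")
    rdm_raw = rdm(np.asarray(raw_z, float), "numeric", label="raw_z")
    rdms_runs = [rdm(np.asarray(L, float), "numeric", label="loadings") for L in loading_runs]
    if run_bounds is not None:
        final_idx = int(np.argmax(run_bounds))
    else:
        final_idx = len(loading_runs) - 1
    rows = []
    for col in characteristics.columns:
        kind = "categorical" if col in categorical else "numeric"
        r_char = rdm(characteristics[col].to_numpy(), kind, label=col)
        tau_raw = kendall_tau_lower(rdm_raw, r_char)
        taus = np.array([kendall_tau_lower(r, r_char) for r in rdms_runs])
        t, p = stats.ttest_1samp(taus, tau_raw)
        rows.append(
            {
                "characteristic": col,
                "tau_factor_mean": float(taus.mean()),
                "tau_factor_sd": float(taus.std(ddof=1)),
                "tau_factor_final": float(taus[final_idx]),
                "tau_raw": tau_raw,
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3:
        return -1.0, 1.0
    zcrit = stats.norm.ppf(0.5 + level / 2)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def clinical_correlations(
    loadings: np.ndarray,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    sites: np.ndarray | None = None,
    min_site_n: int = 4,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-site and pooled loading-symptom Pearson correlations.

    Covariates are regressed out of both loadings and symptom scores
    (within site for the per-site records, pooled after within-site
    residualization for the "overall" records).  Confidence intervals use
    the Fisher z-transform; FDR-BH is applied across the factor x scale
    family separately within each grouping level.
    """
    L = np.asarray(loadings, dtype=float)
    S, K = L.shape
    if len(clinical) != S:
        raise SchemaError("clinical table does not match loadings")
    scales = list(clinical.columns)
    sites = np.asarray(sites) if sites is not None else np.array(["all"] * S)
    rows = []
    resid_L = np.full_like(L, np.nan)
    resid_C = np.full((S, len(scales)), np.nan)
    for site in pd.unique(sites):
        m = sites == site
        if m.sum() < min_site_n:
            continue
        cov_s = covariates.loc[m] if covariates is not None else None
        Ls = residualize(L[m], cov_s)
        Cs = residualize(clinical.loc[m].to_numpy(float), cov_s)
        resid_L[m] = Ls
        resid_C[m] = Cs
        for k in range(K):
            for si, scale in enumerate(scales):
                r = float(np.corrcoef(Ls[:, k], Cs[:, si])[0, 1])
                lo, hi = _fisher_ci(r, int(m.sum()))
                p = stats.pearsonr(Ls[:, k], Cs[:, si]).pvalue
                rows.append(
                    {
                        "site": str(site),
                        "factor": k,
                        "scale": scale,
                        "n": int(m.sum()),
                        "r": r,
                        "ci_low": lo,
                        "ci_high": hi,
                        "p": float(p),
                    }
                )
    ok = ~np.isnan(resid_L[:, 0])
    for k in range(K):
        for si, scale in enumerate(scales):
            r = float(np.corrcoef(resid_L[ok, k], resid_C[ok, si])[0, 1])
            lo, hi = _fisher_ci(r, int(ok.sum()))
            p = stats.pearsonr(resid_L[ok, k], resid_C[ok, si]).pvalue
            rows.append(
                {
                    "site": "overall",
                    "factor": k,
                    "scale": scale,
                    "n": int(ok.sum()),
                    "r": r,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for site in out["site"].unique():
        m = out["site"] == site
        _, p_adj = fdr_bh(out.loc[m, "p"].to_numpy(), q)
        out.loc[m, "p_fdr"] = p_adj
    return out


def glm_contrast(
    y: np.ndarray,
    loadings: np.ndarray,
    H: np.ndarray,
) -> tuple[float, float, float]:
    """OLS of y on (1, p1, p2) with a general linear hypothesis H beta = 0.

    The third loading is implicit through the simplex constraint.  H rows
    such as [0, -1, 1] compare factors; returns (estimate, t, p).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    L = np.asarray(loadings, dtype=float)
    X = sm.add_constant(L[:, :2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("loading design is rank deficient")
    model = sm.OLS(y, X).fit()
    H = np.atleast_2d(np.asarray(H, dtype=float))
    res = model.t_test(H)
    return float(np.squeeze(res.effect)), float(np.squeeze(res.tvalue)), float(np.squeeze(res.pvalue))
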