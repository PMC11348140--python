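"""Latent-factor decomposition of patient synergy-dysfunction patterns.

Patients' synergy matrices are z-scored against the control group; only
synergy *reductions* are kept (positive z reset to zero, negative z made
positive), vectorized over the canonical pair order, and discretized into
counts.  Each patient then plays the role of a "document" whose "words"
are region pairs, and latent Dirichlet allocation recovers K factors:
factor-specific pair-level dysfunction patterns Pr(pair | factor) and
per-patient expression loadings Pr(factor | patient) on the simplex.

Inference is batch variational EM for the smoothed topic model with
symmetric Dirichlet priors alpha (loadings) and eta (patterns).  The
evidence lower bound is tracked every iteration and is nondecreasing; a
collapsed Gibbs sampler is available as an alternative backend for small
corpora.  Factor order is arbitrary per run, so runs and datasets are
compared after optimal one-to-one matching (Hungarian assignment on
pattern correlations).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, psi

from .errors import (
    DegenerateNormalizationError,
    InsufficientSampleError,
    InvalidArgumentError,
)
from .util import lower_pairs, n_pairs, sym_to_vec

# ---------------------------------------------------------------------------
# Containers


@dataclass
class ZScoreMatrix:
    """One patient's synergy matrix z-scored against the control group."""

    subject_id: str
    z: np.ndarray  # (N, N) symmetric


@dataclass
class DocumentMatrix:
    """Discretized synergy-reduction counts, subjects x pairs."""

    counts: np.ndarray  # (S, P) nonnegative integers
    scale: float
    subject_ids: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]


@dataclass
class FactorModel:
    K: int
    patterns: np.ndarray  # (K, P), rows sum to 1
    loadings: np.ndarray  # (S, K), rows sum to 1
    alpha: float
    eta: float
    seed: int
    log_likelihood: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def final_bound(self) -> float:
        return float(self.log_likelihood[-1]) if len(self.log_likelihood) else -np.inf


# ---------------------------------------------------------------------------
# Normalization and document construction


def znormalize_to_controls(scz_matrices, nc_matrices) -> list[ZScoreMatrix]:
    """Per-entry z-score of each patient matrix against the NC distribution.

    Uses the NC sample standard deviation with Bessel correction (n-1).
    """
    nc = np.stack([m.values if hasattr(m, "values") else m for m in nc_matrices])
    if nc.shape[0] < 3:
        raise InsufficientSampleError("need at least 3 NC subjects to z-score")
    mean = nc.mean(axis=0)
    sd = nc.std(axis=0, ddof=1)
    np.fill_diagonal(sd, 1.0)  # diagonal is 0 by convention everywhere
    bad = np.argwhere(sd == 0)
    if len(bad):
        i, j = bad[0]
        raise DegenerateNormalizationError(
            f"NC entry ({i}, {j}) has zero standard deviation"
        )
    out = []
    for m in scz_matrices:
        vals = m.values if hasattr(m, "values") else np.asarray(m)
        sid = getattr(m, "subject_id", "")
        z = (vals - mean) / sd
        np.fill_diagonal(z, 0.0)
        out.append(ZScoreMatrix(subject_id=sid, z=z))
    return out


def prepare_documents(z_matrices: list[ZScoreMatrix], scale: float = 10.0) -> DocumentMatrix:
    """Counts = round(scale * max(0, -z)) over the strict lower triangle.

    Positive z-scores (synergy increases) are reset to zero; reductions
    become nonnegative word counts.  All-zero documents are retained with
    a warning so subject indexing stays aligned.
    """
    if scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    rows, ids = [], []
    for zm in z_matrices:
        w = np.maximum(0.0, -sym_to_vec(zm.z))
        rows.append(np.rint(scale * w).astype(np.int64))
        ids.append(zm.subject_id)
    counts = np.stack(rows)
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    if len(empty):
        warnings.warn(
            f"{len(empty)} subject(s) have no synergy reduction (all-zero "
            f"documents): indices {empty.tolist()}",
            stacklevel=2,
        )
    return DocumentMatrix(counts=counts, scale=scale, subject_ids=ids)


# ---------------------------------------------------------------------------
# Variational EM for the smoothed topic model


def _dirichlet_expectation(x: np.ndarray) -> np.ndarray:
    if x.ndim == 1:
        return psi(x) - psi(x.sum())
    return psi(x) - psi(x.sum(axis=1))[:, None]


def _e_step(X, expElogBeta, alpha, gamma, max_inner=100, tol=1e-4):
    for _ in range(max_inner):
        last = gamma
        expElogTheta = np.exp(_dirichlet_expectation(gamma))
        phinorm = expElogTheta @ expElogBeta + 1e-100
        gamma = alpha + expElogTheta * ((X / phinorm) @ expElogBeta.T)
        if np.mean(np.abs(gamma - last)) < tol:
            break
    expElogTheta = np.exp(_dirichlet_expectation(gamma))
    phinorm = expElogTheta @ expElogBeta + 1e-100
    sstats = expElogBeta * (expElogTheta.T @ (X / phinorm))
    return gamma, sstats, phinorm


def _bound(X, gamma, lam, alpha, eta):
    """Evidence lower bound of the smoothed topic model."""
    S, K = gamma.shape
    P = lam.shape[1]
    ElogTheta = _dirichlet_expectation(gamma)
    ElogBeta = _dirichlet_expectation(lam)
    phinorm = np.exp(ElogTheta) @ np.exp(ElogBeta) + 1e-100
    score = float(np.sum(X * np.log(phinorm)))
    score += float(
        np.sum((alpha - gamma) * ElogTheta)
        + np.sum(gammaln(gamma))
        - np.sum(gammaln(gamma.sum(axis=1)))
        + S * (gammaln(K * alpha) - K * gammaln(alpha))
    )
    score += float(
        np.sum((eta - lam) * ElogBeta)
        + np.sum(gammaln(lam))
        - np.sum(gammaln(lam.sum(axis=1)))
        + K * (gammaln(P * eta) - P * gammaln(eta))
    )
    return score


def fit_lda(
    docs: DocumentMatrix,
    K: int = 3,
    alpha: float | None = None,
    eta: float = 0.01,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    method: str = "vem",
) -> FactorModel:
    """Fit the K-factor topic model to the document matrix.

    alpha defaults to 100/K (a mixed-membership-friendly symmetric prior);
    eta defaults to 0.01 (sparse patterns).  The variational backend is
    deterministic given the seed; the collapsed Gibbs backend is provided
    for small corpora and returns posterior-mean estimates from its final
    sweep state.
    """
    X = np.asarray(docs.counts, dtype=float)
    S, P = X.shape
    if K < 2:
        raise InvalidArgumentError("K must be >= 2")
    if K > S:
        raise InvalidArgumentError("K must not exceed the number of subjects")
    if X.sum() <= 0:
        raise InvalidArgumentError("document matrix has no counts")
    if alpha is None:
        alpha = 100.0 / K
    if method == "gibbs":
        return _fit_gibbs(docs, K, alpha, eta, seed, max_iter)
    if method != "vem":
        raise InvalidArgumentError(f"unknown inference method {method!r}")

    rng = np.random.default_rng(seed)
    lam = rng.gamma(100.0, 0.01, size=(K, P))
    gamma = np.full((S, K), alpha + X.sum() / (S * K))
    trace = []
    for _ in range(max_iter):
        expElogBeta = np.exp(_dirichlet_expectation(lam))
        gamma, sstats, _ = _e_step(X, expElogBeta, alpha, gamma)
        lam = eta + sstats
        trace.append(_bound(X, gamma, lam, alpha, eta))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            break
    patterns = lam / lam.sum(axis=1, keepdims=True)
    loadings = gamma / gamma.sum(axis=1, keepdims=True)
    return FactorModel(
        K=K,
        patterns=patterns,
        loadings=loadings,
        alpha=alpha,
        eta=eta,
        seed=seed,
        log_likelihood=np.asarray(trace),
    )


def _fit_gibbs(docs, K, alpha, eta, seed, n_sweeps):
    """Collapsed Gibbs sampler; intended for small corpora only."""
    X = np.asarray(docs.counts)
    S, P = X.shape
    rng = np.random.default_rng(seed)
    d_idx, w_idx = np.nonzero(X)
    reps = X[d_idx, w_idx]
    d_tok = np.repeat(d_idx, reps)
    w_tok = np.repeat(w_idx, reps)
    z_tok = rng.integers(0, K, size=len(d_tok))
    ndk = np.zeros((S, K))
    nkw = np.zeros((K, P))
    nk = np.zeros(K)
    np.add.at(ndk, (d_tok, z_tok), 1)
    np.add.at(nkw, (z_tok, w_tok), 1)
    np.add.at(nk, z_tok, 1)
    for _ in range(max(1, n_sweeps)):
        for t in range(len(d_tok)):
            d, w, zt = d_tok[t], w_tok[t], z_tok[t]
            ndk[d, zt] -= 1
            nkw[zt, w] -= 1
            nk[zt] -= 1
            p = (ndk[d] + alpha) * (nkw[:, w] + eta) / (nk + P * eta)
            z_new = rng.choice(K, p=p / p.sum())
            z_tok[t] = z_new
            ndk[d, z_new] += 1
            nkw[z_new, w] += 1
            nk[z_new] += 1
    patterns = (nkw + eta) / (nkw + eta).sum(axis=1, keepdims=True)
    loadings = (ndk + alpha) / (ndk + alpha).sum(axis=1, keepdims=True)
    return FactorModel(
        K=K, patterns=patterns, loadings=loadings, alpha=alpha, eta=eta, seed=seed
    )


# ---------------------------------------------------------------------------
# Matching, model selection, derived maps


def match_factors(model_a, model_b) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one factor matching by pattern correlation.

    Returns (perm, r) where model_b's factor ``perm[k]`` matches model_a's
    factor k and r[k] is the Pearson correlation of the matched patterns.
    """
    pa = model_a.patterns if hasattr(model_a, "patterns") else np.asarray(model_a)
    pb = model_b.patterns if hasattr(model_b, "patterns") else np.asarray(model_b)
    if pa.shape[0] != pb.shape[0]:
        raise InvalidArgumentError("models must have equal K")
    K = pa.shape[0]
    corr = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            corr[a, b] = np.corrcoef(pa[a], pb[b])[0, 1]
    row, col = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[row] = col
    return perm, corr[row, col]


def select_k(
    docs: DocumentMatrix,
    K_grid=(2, 3, 4),
    n_splits: int = 10,
    seed: int = 0,
    **lda_kwargs,
) -> tuple[int, "np.ndarray"]:
    """Choose K by split-half pattern-matching stability.

    For each K the subjects are split in half ``n_splits`` times, models
    are fitted to both halves, and the mean matched pattern correlation
    across splits is the stability score; the chosen K maximizes it.
    Returns (K, table) where table rows are (K, mean stability, sd).
    """
    import pandas as pd

    S = docs.n_subjects
    if S < 2 * max(2, min(K_grid)):
        raise InsufficientSampleError("too few subjects for split-half fits")
    rng = np.random.default_rng(seed)
    rows = []
    for K in K_grid:
        vals = []
        for split in range(n_splits):
            perm = rng.permutation(S)
            half = S // 2
            da = DocumentMatrix(docs.counts[perm[:half]], docs.scale)
            db = DocumentMatrix(docs.counts[perm[half : 2 * half]], docs.scale)
            ma = fit_lda(da, K=K, seed=int(rng.integers(2**31)), **lda_kwargs)
            mb = fit_lda(db, K=K, seed=int(rng.integers(2**31)), **lda_kwargs)
            _, r = match_factors(ma, mb)
            vals.append(float(np.mean(r)))
        rows.append({"K": K, "stability": float(np.mean(vals)), "sd": float(np.std(vals))})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["stability"].idxmax(), "K"])
    return chosen, table


def factor_map(model: FactorModel, k: int) -> np.ndarray:
    """Regional dysfunction map of factor k: sum of its pattern over the
    pairs containing each region."""
    if not 0 <= k < model.K:
        raise InvalidArgumentError(f"factor index {k} out of range")
    P = model.patterns.shape[1]
    n = int(round((1 + np.sqrt(1 + 8 * P)) / 2))
    if n_pairs(n) != P:
        raise InvalidArgumentError("pattern length is not a pair count")
    i, j = lower_pairs(n)
    out = np.zeros(n)
    np.add.at(out, i, model.patterns[k])
    np.add.at(out, j, model.patterns[k])
    return out


def assign_subtype(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtype = argmax loading per subject; ties go to the lowest factor
    index and are flagged."""
    L = np.asarray(loadings, dtype=float)
    labels = L.argmax(axis=1)
    mx = L.max(axis=1, keepdims=True)
    ties = (L == mx).sum(axis=1) > 1
    return labels, ties


def top_sections_mask(
    map_values: np.ndarray,
    n_sections: int = 20,
    top_fraction: float = 0.2,
) -> tuple[np.ndarray, bool]:
    """Rank regions, cut into ``n_sections`` rank sections, return the top
    fraction of sections as boolean masks (highest first).

    Ties across a section boundary are broken by region index and
    flagged.  When N is not divisible by n_sections the sections are
    sized by quantile rank (np.array_split semantics).
    """
    v = np.asarray(map_values, dtype=float)
    order = np.lexsort((np.arange(len(v)), -v))  # descending, index tiebreak
    sections = np.array_split(order, n_sections)
    n_top = int(round(n_sections * top_fraction))
    masks = np.zeros((n_top, len(v)), dtype=bool)
    tie_flag = False
    for s in range(n_top):
        masks[s, sections[s]] = True
        # a tie crosses the boundary when the cut separates equal values
        if s + 1 < len(sections) and len(sections[s + 1]):
            if v[sections[s][-1]] == v[sections[s + 1][0]]:
                tie_flag = True
    return masks, tie_flag
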