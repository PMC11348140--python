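"""Minimal (mu/mu_w, lambda) covariance-matrix-adaptation evolution strategy.

Standard rank-mu + rank-one update with cumulative step-size adaptation,
following the canonical tutorial formulation.  Box constraints are
enforced by projecting candidates onto the feasible box before
evaluation.  Deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FittingFailedError


@dataclass
class CMAResult:
    x_best: np.ndarray
    f_best: float
    history: list = field(default_factory=list)  # best f per generation
    n_evals: int = 0


def cma_es(
    objective,
    x0: np.ndarray,
    sigma0: float,
    bounds: np.ndarray | None = None,
    popsize: int | None = None,
    max_generations: int = 64,
    seed: int = 0,
) -> CMAResult:
    """Minimize ``objective`` starting from x0 with initial step sigma0.

    ``bounds`` is an (n, 2) array of [low, high] per coordinate; samples
    are clipped to it before evaluation (the clipped point is the
    candidate).  With ``max_generations=0`` the initial point is simply
    evaluated and returned.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    rng = np.random.default_rng(seed)
    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(lam / 2 + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    def clip(x):
        if bounds is None:
            return x
        return np.clip(x, bounds[:, 0], bounds[:, 1])

    m = clip(x0.copy())
    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)
    f_best = float(objective(m))
    x_best = m.copy()
    n_evals = 1
    history = [f_best]
    if not np.isfinite(f_best) and max_generations == 0:
        raise FittingFailedError("initial candidate is non-finite")

    for gen in range(max_generations):
        evals, vals = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        BD = vals * np.sqrt(evals)
        z = rng.standard_normal((lam, n))
        y = z @ BD.T
        xs = clip(m + sigma * y)
        fs = np.array([objective(x) for x in xs])
        n_evals += lam
        finite = np.isfinite(fs)
        if not finite.any():
            raise FittingFailedError(f"all candidates non-finite at generation {gen}")
        fs = np.where(finite, fs, np.inf)
        order = np.argsort(fs)
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs[order[0]].copy()
        history.append(f_best)

        y_sel = (xs[order[:mu]] - m) / sigma
        y_w = w @ y_sel
        m = clip(m + sigma * y_w)

        inv_sqrt_C = vals @ np.diag(evals**-0.5) @ vals.T
        p_sigma = (1 - cs) * p_sigma + np.sqrt(cs * (2 - cs) * mu_eff) * (
            inv_sqrt_C @ y_w
        )
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1)))
            / chi_n
            < 1.4 + 2 / (n + 1)
        )
        p_c = (1 - cc) * p_c + h_sigma * np.sqrt(cc * (2 - cc) * mu_eff) * y_w
        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(w, y_sel))
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(p_c, p_c) + (1 - h_sigma) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        C = (C + C.T) / 2
        sigma *= np.exp((cs / damps) * (np.linalg.norm(p_sigma) / chi_n - 1))
        sigma = min(sigma, 1e6)

    return CMAResult(x_best=x_best, f_best=f_best, history=history, n_evals=n_evals)
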