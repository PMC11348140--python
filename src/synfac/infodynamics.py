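"""Gaussian integrated information decomposition for pairs of BOLD series.

For every unordered pair of regions the time-delayed mutual information
between the joint past ``(X1_t, X2_t)`` and the joint future
``(X1_{t+tau}, X2_{t+tau})`` is decomposed into sixteen information atoms
indexed by a pair of partial-information nodes (Red, Un1, Un2, Syn) — one
node describing how the information is carried in the past, one in the
future.  Redundancy between source collections is measured with the
minimum-mutual-information (MMI) functional, for which the double
redundancy of a node pair is simply the minimum over the single-source
lagged MIs.  Under a jointly Gaussian model every required mutual
information has the closed form

    I(A; B) = 1/2 * ln( det(S_A) * det(S_B) / det(S_{A u B}) )

so the whole decomposition reduces to determinants of sub-blocks of the
4x4 lagged covariance followed by one fixed 16x16 linear solve (the
zeta/Moebius system of the product redundancy lattice).

The two atoms carried forward by the rest of the pipeline are the
persistent synergy ``Syn->Syn`` and the persistent redundancy
``Red->Red``; all sixteen are returned for completeness and always sum to
the time-delayed mutual information.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import (
    DegenerateSeriesError,
    InternalInconsistencyError,
    InvalidArgumentError,
    SingularCovarianceError,
)
from .util import lower_pairs, zscore_columns

# ---------------------------------------------------------------------------
# Redundancy-lattice bookkeeping.
#
# Nodes of the two-source PID lattice, ordered Red <= {Un1, Un2} <= Syn.
# Each node is identified with the source collections it represents:
# Red with both singletons, Un1/Un2 with one singleton, Syn with the joint.
NODES = ("red", "un1", "un2", "syn")

# Source collections per node; channel indices are 0 and 1.
_NODE_SOURCES = {
    "red": ((0,), (1,)),
    "un1": ((0,),),
    "un2": ((1,),),
    "syn": ((0, 1),),
}

# Partial order on nodes: _LEQ[a][b] is True when a <= b in the lattice.
_LEQ = {
    "red": {"red", "un1", "un2", "syn"},
    "un1": {"un1", "syn"},
    "un2": {"un2", "syn"},
    "syn": {"syn"},
}


def atom_names() -> list[tuple[str, str]]:
    """The sixteen (past-node, future-node) atom labels in canonical order."""
    return [(a, b) for a in NODES for b in NODES]


def _zeta_matrix() -> np.ndarray:
    """16x16 matrix Z with Z[(a,b),(a',b')] = 1 iff a'<=a and b'<=b.

    ``Z @ atoms`` yields the cumulative (double-redundancy) values, so
    atoms are recovered as ``solve(Z, R)`` — Moebius inversion on the
    product lattice expressed as one linear system.
    """
    names = atom_names()
    z = np.zeros((16, 16))
    for r, (a, b) in enumerate(names):
        for c, (a2, b2) in enumerate(names):
            z[r, c] = 1.0 if (a2 in _down(a) and b2 in _down(b)) else 0.0
    return z


def _down(node: str) -> set[str]:
    """All nodes below-or-equal to ``node`` in the lattice."""
    return {m for m in NODES if node in _LEQ[m]}


_ZETA = _zeta_matrix()
_ZETA_INV = np.linalg.inv(_ZETA)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class RegionalTimeSeries:
    """One subject's time x region BOLD matrix with its sampling interval."""

    subject_id: str
    data: np.ndarray  # (T, N)
    dt: float = 2.0  # seconds per sample (TR)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be a T x N matrix")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("time series contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class LaggedCovariance:
    """Covariance of (X1_t, X2_t, X1_{t+tau}, X2_{t+tau})."""

    tau: int
    cov: np.ndarray  # (4, 4)

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (4, 4):
            raise InvalidArgumentError("cov must be 4x4")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise InvalidArgumentError("cov must be symmetric")


@dataclass
class PhIDAtoms:
    """The sixteen information atoms of one region pair (nats)."""

    atoms: dict  # {(past_node, future_node): value}
    tdmi: float

    @property
    def synergy(self) -> float:
        """Persistent synergy, the Syn->Syn atom."""
        return self.atoms[("syn", "syn")]

    @property
    def redundancy(self) -> float:
        """Persistent redundancy, the Red->Red atom."""
        return self.atoms[("red", "red")]


@dataclass
class InteractionMatrix:
    """Symmetric region x region matrix of one interaction kind."""

    kind: str  # "synergy" | "redundancy" | "fc"
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("synergy", "redundancy", "fc"):
            raise InvalidArgumentError(f"unknown interaction kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Estimation


def lagged_covariance(x: np.ndarray, y: np.ndarray, tau: int) -> LaggedCovariance:
    """Sample lagged covariance of two z-scored series.

    Stacks ``(x_t, y_t, x_{t+tau}, y_{t+tau})`` over all admissible t and
    returns its sample covariance.  Both series are z-scored internally;
    Gaussian mutual information is invariant to this rescaling.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have equal length")
    if tau < 0:
        raise InvalidArgumentError("tau must be >= 0")
    if len(x) - tau < 20:
        raise InvalidArgumentError("need at least 20 usable time points")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSeriesError("zero-variance input series")
    x = (x - x.mean()) / x.std(ddof=1)
    y = (y - y.mean()) / y.std(ddof=1)
    if tau == 0:
        stacked = np.column_stack([x, y, x, y])
    else:
        stacked = np.column_stack([x[:-tau], y[:-tau], x[tau:], y[tau:]])
    return LaggedCovariance(tau=tau, cov=np.cov(stacked.T, ddof=1))


def _subdet(cov: np.ndarray, idx: tuple[int, ...]) -> float:
    sub = cov[np.ix_(idx, idx)]
    return float(np.linalg.det(sub))


def gaussian_mi(cov: LaggedCovariance | np.ndarray, A, B) -> float:
    """Gaussian mutual information between coordinate sets A and B (nats)."""
    c = cov.cov if isinstance(cov, LaggedCovariance) else np.asarray(cov, float)
    A, B = tuple(sorted(A)), tuple(sorted(B))
    if not A or not B or set(A) & set(B):
        raise InvalidArgumentError("A and B must be disjoint nonempty index sets")
    dA, dB = _subdet(c, A), _subdet(c, B)
    dAB = _subdet(c, A + B)
    if dAB <= 1e-300 or dA <= 1e-300 or dB <= 1e-300:
        raise SingularCovarianceError(
            f"singular covariance block for A={A}, B={B} "
            "(duplicated or degenerate channels?)"
        )
    return max(0.0, 0.5 * np.log(dA * dB / dAB))


def _mi_table(cov: np.ndarray) -> np.ndarray:
    """3x3 table of I(past collection; future collection).

    Collections indexed 0:{ch1}, 1:{ch2}, 2:{ch1,ch2}; past coordinates are
    (0, 1), future coordinates are (2, 3) of the 4x4 covariance.
    """
    past = [(0,), (1,), (0, 1)]
    fut = [(2,), (3,), (2, 3)]
    out = np.empty((3, 3))
    for i, a in enumerate(past):
        for j, b in enumerate(fut):
            out[i, j] = gaussian_mi(cov, a, b)
    return out


def _cumulative_from_mi(mi: np.ndarray) -> np.ndarray:
    """The sixteen MMI double-redundancy values from the 3x3 MI table.

    For a node pair (alpha, beta) the MMI double redundancy is the minimum
    of I(a; b) over source collections a of alpha and b of beta.
    """
    coll_idx = {(0,): 0, (1,): 1, (0, 1): 2}
    r = np.empty(16)
    for k, (a, b) in enumerate(atom_names()):
        vals = [
            mi[coll_idx[sa], coll_idx[sb]]
            for sa, sb in product(_NODE_SOURCES[a], _NODE_SOURCES[b])
        ]
        r[k] = min(vals)
    return r


def double_redundancy_mmi(cov: LaggedCovariance) -> float:
    """MMI double redundancy: min over the four single-channel lagged MIs."""
    c = cov.cov if isinstance(cov, LaggedCovariance) else np.asarray(cov, float)
    return min(
        gaussian_mi(c, (i,), (j,)) for i in (0, 1) for j in (2, 3)
    )


def phid_decompose(cov: LaggedCovariance) -> PhIDAtoms:
    """Solve the sixteen-atom decomposition for one lagged covariance.

    The cumulative value of each node pair (its MMI double redundancy) is
    the sum of all atoms at-or-below it in the product lattice; inverting
    that fixed linear system yields the atoms.  Marginal MIs are clamped
    at zero; atoms themselves may legitimately be negative under MMI.
    """
    c = cov.cov if isinstance(cov, LaggedCovariance) else np.asarray(cov, float)
    mi = _mi_table(c)
    r = _cumulative_from_mi(mi)
    try:
        atoms = np.linalg.solve(_ZETA, r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - fixed matrix
        raise InternalInconsistencyError("zeta system unsolvable") from exc
    names = atom_names()
    return PhIDAtoms(atoms=dict(zip(names, atoms)), tdmi=float(mi[2, 2]))


# ---------------------------------------------------------------------------
# Whole-matrix (per-subject) computation, vectorized over pairs.


def _batch_cov4(data: np.ndarray, tau: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack of 4x4 lagged covariances for every region pair.

    Returns (C, i, j) where C has shape (P, 4, 4) with coordinate order
    (X_i(t), X_j(t), X_i(t+tau), X_j(t+tau)) and (i, j) is the canonical
    pair order.
    """
    z = zscore_columns(data)
    n = z.shape[1]
    if tau == 0:
        big = np.cov(np.hstack([z, z]).T, ddof=1)
    else:
        big = np.cov(np.hstack([z[:-tau], z[tau:]]).T, ddof=1)
    i, j = lower_pairs(n)
    idx = np.stack([i, j, i + n, j + n], axis=1)  # (P, 4)
    C = big[idx[:, :, None], idx[:, None, :]]
    return C, i, j


def _batch_phid(C: np.ndarray) -> np.ndarray:
    """Vectorized sixteen-atom decomposition for a (P, 4, 4) stack.

    Returns atoms with shape (P, 16) in :func:`atom_names` order.
    """
    d = np.einsum("pii->pi", C)  # variances
    if np.any(d <= 0):
        raise SingularCovarianceError("non-positive variance in lagged covariance")

    def det2(a, b):
        return C[:, a, a] * C[:, b, b] - C[:, a, b] ** 2

    d01, d23 = det2(0, 1), det2(2, 3)
    d02, d03, d12, d13 = det2(0, 2), det2(0, 3), det2(1, 2), det2(1, 3)

    def det3(keep):
        k = list(keep)
        return np.linalg.det(C[:, k][:, :, k])

    d012, d013 = det3((0, 1, 2)), det3((0, 1, 3))
    d023, d123 = det3((0, 2, 3)), det3((1, 2, 3))
    d0123 = np.linalg.det(C)

    small = 1e-300
    for arr in (d01, d23, d012, d013, d023, d123, d0123):
        if np.any(arr <= small):
            raise SingularCovarianceError(
                "singular joint covariance block (duplicated regions?)"
            )

    def mi(num1, num2, den):
        return np.maximum(0.0, 0.5 * np.log(num1 * num2 / den))

    mi_tab = np.empty((C.shape[0], 3, 3))
    mi_tab[:, 0, 0] = mi(d[:, 0], d[:, 2], d02)
    mi_tab[:, 0, 1] = mi(d[:, 0], d[:, 3], d03)
    mi_tab[:, 0, 2] = mi(d[:, 0], d23, d023)
    mi_tab[:, 1, 0] = mi(d[:, 1], d[:, 2], d12)
    mi_tab[:, 1, 1] = mi(d[:, 1], d[:, 3], d13)
    mi_tab[:, 1, 2] = mi(d[:, 1], d23, d123)
    mi_tab[:, 2, 0] = mi(d01, d[:, 2], d012)
    mi_tab[:, 2, 1] = mi(d01, d[:, 3], d013)
    mi_tab[:, 2, 2] = mi(d01, d23, d0123)

    coll_idx = {(0,): 0, (1,): 1, (0, 1): 2}
    R = np.empty((C.shape[0], 16))
    for k, (a, b) in enumerate(atom_names()):
        cand = [
            mi_tab[:, coll_idx[sa], coll_idx[sb]]
            for sa, sb in product(_NODE_SOURCES[a], _NODE_SOURCES[b])
        ]
        R[:, k] = np.min(cand, axis=0) if len(cand) > 1 else cand[0]
    return R @ _ZETA_INV.T


_SYN_IDX = atom_names().index(("syn", "syn"))
_RED_IDX = atom_names().index(("red", "red"))


def pairwise_interaction_matrices(
    ts: RegionalTimeSeries, tau: int = 1
) -> tuple[InteractionMatrix, InteractionMatrix]:
    """Persistent synergy and redundancy matrices for one subject.

    The decomposition is invariant to relabeling the two channels of a
    pair, so both matrices are symmetric by construction; diagonals are 0
    by convention.
    """
    if ts.n_regions < 2:
        raise InvalidArgumentError("need at least two regions")
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateSeriesError(f"degenerate (constant) region series: {bad}")
    C, i, j = _batch_cov4(ts.data, tau)
    atoms = _batch_phid(C)
    n = ts.n_regions
    syn = np.zeros((n, n))
    red = np.zeros((n, n))
    syn[i, j] = syn[j, i] = atoms[:, _SYN_IDX]
    red[i, j] = red[j, i] = atoms[:, _RED_IDX]
    return (
        InteractionMatrix("synergy", syn, ts.subject_id),
        InteractionMatrix("redundancy", red, ts.subject_id),
    )


def var1_pair_covariances(A: np.ndarray, noise_cov: np.ndarray | None = None):
    """Analytic lagged covariances of every region pair of a stable VAR(1).

    For x_{t+1} = A x_t + eps with eps ~ N(0, Q) the stationary covariance
    S0 solves the discrete Lyapunov equation S0 = A S0 A' + Q and the
    lag-1 cross covariance cov(x_t, x_{t+1}) equals S0 A'.  Returns
    (C, i, j) with C of shape (P, 4, 4) in the same layout as
    :func:`_batch_cov4`.
    """
    from scipy.linalg import solve_discrete_lyapunov

    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        raise InvalidArgumentError("VAR(1) coupling matrix is not stable")
    Q = np.eye(n) if noise_cov is None else np.asarray(noise_cov, float)
    S0 = solve_discrete_lyapunov(A, Q)
    Sl = S0 @ A.T  # cov(x_t, x_{t+1})
    i, j = lower_pairs(n)
    P = len(i)
    C = np.empty((P, 4, 4))
    C[:, 0, 0] = S0[i, i]
    C[:, 1, 1] = S0[j, j]
    C[:, 0, 1] = C[:, 1, 0] = S0[i, j]
    C[:, 2, 2] = S0[i, i]
    C[:, 3, 3] = S0[j, j]
    C[:, 2, 3] = C[:, 3, 2] = S0[i, j]
    C[:, 0, 2] = C[:, 2, 0] = Sl[i, i]
    C[:, 0, 3] = C[:, 3, 0] = Sl[i, j]
    C[:, 1, 2] = C[:, 2, 1] = Sl[j, i]
    C[:, 1, 3] = C[:, 3, 1] = Sl[j, j]
    return C, i, j


def analytic_pair_synergy(A: np.ndarray) -> np.ndarray:
    """Population persistent-synergy value of every pair of a VAR(1) law."""
    C, _, _ = var1_pair_covariances(A)
    return _batch_phid(C)[:, _SYN_IDX]


def functional_connectivity(ts: RegionalTimeSeries) -> InteractionMatrix:
    """Pearson-correlation FC matrix with the diagonal zeroed."""
    if ts.n_regions < 2:
        raise InvalidArgumentError("need at least two regions")
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateSeriesError(f"zero-variance region series: {bad}")
    fc = np.corrcoef(ts.data.T)
    np.fill_diagonal(fc, 0.0)
    return InteractionMatrix("fc", fc, ts.subject_id)
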