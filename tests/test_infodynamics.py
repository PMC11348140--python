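"""Information-decomposition unit tests: closed forms, lattice constraints,
and the independent Moebius-inversion oracle."""
import numpy as np
import pytest
from itertools import product

from synfac.errors import (
    DegenerateSeriesError,
    InvalidArgumentError,
    SingularCovarianceError,
)
from synfac.infodynamics import (
    LaggedCovariance,
    NODES,
    RegionalTimeSeries,
    _NODE_SOURCES,
    _batch_cov4,
    _batch_phid,
    atom_names,
    double_redundancy_mmi,
    functional_connectivity,
    gaussian_mi,
    lagged_covariance,
    pairwise_interaction_matrices,
    phid_decompose,
    var1_pair_covariances,
)
from synfac.util import lower_pairs, zscore_columns

from conftest import random_lagged_cov


def ar1_cross_cov(phi1, phi2, rho=0.0):
    """Analytic lagged covariance of two AR(1) channels.

    With rho=0 the channels are fully independent; channel variances are
    stationary 1/(1-phi^2).
    """
    v1, v2 = 1 / (1 - phi1**2), 1 / (1 - phi2**2)
    c = np.zeros((4, 4))
    c[0, 0] = c[2, 2] = v1
    c[1, 1] = c[3, 3] = v2
    c[0, 2] = c[2, 0] = phi1 * v1
    c[1, 3] = c[3, 1] = phi2 * v2
    return c


def identical_channels_cov(phi, eps=1e-5):
    """Two (near-)identical AR(1) channels; eps avoids exact singularity."""
    v = 1 / (1 - phi**2)
    c = np.full((4, 4), 0.0)
    c[0, 0] = c[2, 2] = v
    c[1, 1] = c[3, 3] = v + eps**2
    c[0, 1] = c[1, 0] = c[2, 3] = c[3, 2] = v
    for a in (0, 1):
        for b in (2, 3):
            c[a, b] = c[b, a] = phi * v
    return c


class TestGaussianMI:
    def test_uncorrelated_channels_have_zero_mi(self):
        c = np.eye(4)
        assert gaussian_mi(c, (0,), (1,)) == 0.0

    def test_bivariate_closed_form(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.5
        expected = 0.5 * np.log(1 / (1 - 0.25))
        assert gaussian_mi(c, (0,), (1,)) == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlation_is_singular(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 1.0
        with pytest.raises(SingularCovarianceError):
            gaussian_mi(c, (0,), (1,))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gaussian_mi(np.eye(4), (0, 1), (1, 2))


class TestLaggedCovariance:
    def test_same_series_zero_lag_unit_cross_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        cov = lagged_covariance(x, x, tau=0)
        assert cov.cov[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_off_diagonals_vanish(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        cov = lagged_covariance(x, y, tau=1)
        off = cov.cov[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 4 / np.sqrt(10_000))

    def test_ar1_lag_autocovariance(self):
        rng = np.random.default_rng(2)
        phi, T = 0.5, 200_000
        x = np.empty(T)
        x[0] = rng.normal()
        eps = rng.normal(size=T)
        for t in range(1, T):
            x[t] = phi * x[t - 1] + eps[t]
        cov = lagged_covariance(x, rng.normal(size=T), tau=1)
        assert cov.cov[0, 2] == pytest.approx(phi, abs=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            lagged_covariance(np.ones(100), np.arange(100.0), tau=1)


class TestDoubleRedundancy:
    def test_independent_channels_zero(self):
        cov = LaggedCovariance(1, ar1_cross_cov(0.5, 0.7))
        assert double_redundancy_mmi(cov) == 0.0

    def test_identical_channels_closed_form(self):
        phi = 0.6
        cov = LaggedCovariance(1, identical_channels_cov(phi))
        expected = 0.5 * np.log(1 / (1 - phi**2))
        assert double_redundancy_mmi(cov) == pytest.approx(expected, abs=1e-6)

    def test_never_exceeds_any_single_channel_mi(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = random_lagged_cov(rng)
            red = double_redundancy_mmi(LaggedCovariance(1, c))
            for i in (0, 1):
                for j in (2, 3):
                    assert red <= gaussian_mi(c, (i,), (j,)) + 1e-12


def mobius_atoms(cov):
    """Independent oracle: recursive Moebius inversion on the product lattice."""
    below = {
        "red": [], "un1": ["red"], "un2": ["red"], "syn": ["red", "un1", "un2"]
    }

    def cumulative(a, b):
        return min(
            gaussian_mi(cov, sa, tuple(x + 2 for x in sb))
            for sa, sb in product(_NODE_SOURCES[a], _NODE_SOURCES[b])
        )

    atoms = {}

    def strict_below(a, b):
        out = []
        for a2 in below[a] + [a]:
            for b2 in below[b] + [b]:
                if (a2, b2) != (a, b):
                    out.append((a2, b2))
        return out

    for a, b in sorted(
        [(x, y) for x in NODES for y in NODES],
        key=lambda nb: len(below[nb[0]]) + len(below[nb[1]]),
    ):
        atoms[(a, b)] = cumulative(a, b) - sum(
            atoms[nb] for nb in strict_below(a, b)
        )
    return atoms


class TestPhIDDecompose:
    def test_conservation_against_independent_tdmi(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            c = random_lagged_cov(rng)
            atoms = phid_decompose(LaggedCovariance(1, c))
            tdmi = gaussian_mi(c, (0, 1), (2, 3))
            assert sum(atoms.atoms.values()) == pytest.approx(tdmi, abs=1e-8)

    def test_constraint_reproduction(self):
        """Every measured cumulative equals the matching partial atom sum."""
        rng = np.random.default_rng(5)
        c = random_lagged_cov(rng)
        atoms = phid_decompose(LaggedCovariance(1, c))
        down = {"red": {"red"}, "un1": {"red", "un1"}, "un2": {"red", "un2"},
                "syn": {"red", "un1", "un2", "syn"}}
        for a in NODES:
            for b in NODES:
                measured = min(
                    gaussian_mi(c, sa, tuple(x + 2 for x in sb))
                    for sa, sb in product(_NODE_SOURCES[a], _NODE_SOURCES[b])
                )
                partial = sum(
                    v for (a2, b2), v in atoms.atoms.items()
                    if a2 in down[a] and b2 in down[b]
                )
                assert partial == pytest.approx(measured, abs=1e-8)

    def test_matches_mobius_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            c = random_lagged_cov(rng)
            solved = phid_decompose(LaggedCovariance(1, c)).atoms
            oracle = mobius_atoms(c)
            for key in atom_names():
                assert solved[key] == pytest.approx(oracle[key], abs=1e-10)

    def test_independent_channels_analytic_solution(self):
        """For independent AR(1) channels the MMI solution has Red->Red = 0,
        unique self-information on the Un diagonal, and the residual TDMI
        concentrated in Syn->Syn (2 min m), offset by negative mixed atoms."""
        phi1, phi2 = 0.4, 0.7
        m1 = 0.5 * np.log(1 / (1 - phi1**2))
        m2 = 0.5 * np.log(1 / (1 - phi2**2))
        mn = min(m1, m2)
        atoms = phid_decompose(LaggedCovariance(1, ar1_cross_cov(phi1, phi2))).atoms
        assert atoms[("red", "red")] == pytest.approx(0.0, abs=1e-10)
        assert atoms[("un1", "un1")] == pytest.approx(m1, abs=1e-10)
        assert atoms[("un2", "un2")] == pytest.approx(m2, abs=1e-10)
        assert atoms[("red", "syn")] == pytest.approx(mn, abs=1e-10)
        assert atoms[("syn", "red")] == pytest.approx(mn, abs=1e-10)
        assert atoms[("un1", "syn")] == pytest.approx(-mn, abs=1e-10)
        assert atoms[("syn", "syn")] == pytest.approx(2 * mn, abs=1e-10)

    def test_identical_channels_analytic_limit(self):
        phi = 0.6
        atoms = phid_decompose(LaggedCovariance(1, identical_channels_cov(phi)))
        assert atoms.redundancy == pytest.approx(
            0.5 * np.log(1 / (1 - phi**2)), abs=1e-6
        )
        assert atoms.synergy == pytest.approx(0.0, abs=1e-6)


class TestEstimatorConsistency:
    def test_sample_atoms_converge_to_analytic_var1(self):
        rng = np.random.default_rng(7)
        n = 4
        A = rng.normal(0, 0.25, (n, n))
        np.fill_diagonal(A, 0.4)
        A /= 1.05 * np.max(np.abs(np.linalg.eigvals(A))) / 0.8
        T = 50_000
        x = np.zeros(n)
        xs = np.empty((T, n))
        eps = rng.normal(size=(T + 200, n))
        for t in range(T + 200):
            x = A @ x + eps[t]
            if t >= 200:
                xs[t - 200] = x
        C_hat, _, _ = _batch_cov4(xs, 1)
        C_true, _, _ = var1_pair_covariances(A)
        atoms_hat = _batch_phid(C_hat)
        atoms_true = _batch_phid(C_true)
        assert np.max(np.abs(atoms_hat - atoms_true)) < 0.01


class TestPairwiseMatrices:
    def test_channel_order_invariance(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(300, 5))
        data[:, 1] += 0.5 * np.roll(data[:, 0], 1)
        syn, red = pairwise_interaction_matrices(RegionalTimeSeries("s", data))
        flipped = data[:, ::-1]
        syn2, red2 = pairwise_interaction_matrices(RegionalTimeSeries("s", flipped))
        assert np.allclose(syn.values, syn.values.T)
        assert np.allclose(syn.values[::-1, ::-1], syn2.values, atol=1e-12)
        assert np.allclose(red.values[::-1, ::-1], red2.values, atol=1e-12)

    def test_degenerate_region_named(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(100, 4))
        data[:, 2] = 3.0
        with pytest.raises(DegenerateSeriesError, match="2"):
            pairwise_interaction_matrices(RegionalTimeSeries("s", data))

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(400, 4))
        data[:, 1] += 0.6 * np.roll(data[:, 2], 1)
        z = zscore_columns(data)
        C, i, j = _batch_cov4(data, 1)
        batch = _batch_phid(C)
        for p in range(len(i)):
            cov = lagged_covariance(z[:, i[p]], z[:, j[p]], 1)
            scalar = phid_decompose(cov)
            names = atom_names()
            assert batch[p, names.index(("syn", "syn"))] == pytest.approx(
                scalar.synergy, abs=1e-10
            )
            assert batch[p, names.index(("red", "red"))] == pytest.approx(
                scalar.redundancy, abs=1e-10
            )


class TestFunctionalConnectivity:
    def test_duplicated_regions_fully_correlated(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=300)
        data = np.column_stack([x, x, rng.normal(size=300)])
        fc = functional_connectivity(RegionalTimeSeries("s", data))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert np.all(np.abs(fc.values) <= 1.0 + 1e-12)
        assert np.all(np.diag(fc.values) == 0)

    def test_zero_variance_region_rejected(self):
        data = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.raises(DegenerateSeriesError):
            functional_connectivity(RegionalTimeSeries("s", data))
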