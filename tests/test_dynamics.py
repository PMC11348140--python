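"""Mean-field model tests: transfer-function limits, fixed points,
hemodynamics, FCD, the fit cost, and the evolution strategy."""
import numpy as np
import pytest
from scipy.optimize import brentq

from synfac._cmaes import cma_es
from synfac.dynamics import (
    A_GAIN,
    B_THRESH,
    D_SLOPE,
    GAMMA_KIN,
    J_SYN,
    PMFMParams,
    TAU_S,
    fcd,
    fit_cost,
    hemodynamics,
    param_diff_factor_corr,
    regional_params,
    simulate_bold,
    simulate_mfm,
    transfer_rate,
)
from synfac.errors import InvalidArgumentError
from synfac.synthdata import make_parcellation, simulate_structural


@pytest.fixture(scope="module")
def setup():
    parc = make_parcellation(20, 0, seed=2)
    sc, mye, grad = simulate_structural(parc, density=0.15, seed=2)
    params = PMFMParams(a_w=0.08, b_w=-0.05, c_w=0.3, a_i=0.04, b_i=0.02,
                        c_i=0.33, c_s=0.004, G=0.6)
    return parc, sc, mye, grad, params


class TestTransferRate:
    def test_removable_singularity(self):
        assert transfer_rate(B_THRESH / A_GAIN) == pytest.approx(1.0 / D_SLOPE)

    def test_monotone_increasing(self):
        xs = np.linspace(0.0, 1.0, 200)
        h = transfer_rate(xs)
        assert np.all(np.diff(h) > 0)

    def test_continuous_through_singularity(self):
        x0 = B_THRESH / A_GAIN
        near = transfer_rate(np.array([x0 - 1e-7, x0, x0 + 1e-7]))
        assert np.ptp(near) < 1e-4


class TestRegionalParams:
    def test_constant_when_slopes_zero(self):
        mye = np.random.default_rng(0).normal(size=10)
        grad = np.random.default_rng(1).normal(size=10)
        W, I, s = regional_params(mye, grad, PMFMParams())
        assert np.allclose(W, 0.5) and np.allclose(I, 0.3)
        assert np.allclose(s, 0.005)

    def test_one_hot_map_shifts_single_region(self):
        mye = np.zeros(6)
        mye[2] = 1.0
        W, _, _ = regional_params(mye, np.zeros(6),
                                  PMFMParams(a_w=0.2, c_w=0.5))
        assert W[2] == pytest.approx(0.7)
        assert np.allclose(np.delete(W, 2), 0.5)

    def test_hand_computed_three_regions(self):
        mye = np.array([1.0, -1.0, 0.0])
        grad = np.array([0.0, 1.0, -1.0])
        p = PMFMParams(a_w=0.1, b_w=0.2, c_w=0.5)
        W, _, _ = regional_params(mye, grad, p)
        assert np.allclose(W, [0.6, 0.6, 0.3])

    def test_floor_applied(self):
        W, _, s = regional_params(np.array([-100.0]), np.zeros(1),
                                  PMFMParams(a_w=1.0))
        assert W[0] == 1e-4


class TestSimulateMFM:
    def test_fixed_point_persistence_without_noise(self, setup):
        _, sc, mye, grad, params = setup
        W, I, _ = regional_params(mye, grad, params)
        settle = simulate_mfm(sc, W, I, 0.0, params.G, duration=60.0, seed=0)
        s_star = settle.S_trace[-1]
        hold = simulate_mfm(sc, W, I, 0.0, params.G, duration=100.0, seed=0,
                            s_init=s_star)
        assert np.max(np.abs(hold.S_trace[-1] - s_star)) < 1e-6

    def test_isolated_region_matches_root_oracle(self, setup):
        _, sc, mye, grad, params = setup
        W, I, _ = regional_params(mye, grad, params)
        sim = simulate_mfm(np.zeros_like(sc), W, I, 0.0, 0.0, duration=80.0,
                           seed=0)
        for k in (0, 5, 11):
            def resid(s):
                x = W[k] * J_SYN * s + I[k]
                return -s / TAU_S + GAMMA_KIN * (1 - s) * transfer_rate(x)
            root = brentq(resid, 1e-12, 1 - 1e-12)
            assert sim.S_trace[-1, k] == pytest.approx(root, abs=1e-6)

    def test_state_bounded(self, setup):
        _, sc, mye, grad, params = setup
        W, I, s = regional_params(mye, grad, params)
        sim = simulate_mfm(sc, W, I, 0.01, params.G, duration=30.0, seed=1)
        assert np.all(sim.S_trace >= 0.0) and np.all(sim.S_trace <= 1.0)

    def test_step_size_convergence(self, setup):
        _, sc, mye, grad, params = setup
        W, I, _ = regional_params(mye, grad, params)
        a = simulate_mfm(sc, W, I, 0.0, params.G, duration=50.0, seed=0,
                         dt=0.01)
        b = simulate_mfm(sc, W, I, 0.0, params.G, duration=50.0, seed=0,
                         dt=0.005)
        assert np.max(np.abs(a.S_trace[-1] - b.S_trace[-1])) < 1e-4

    def test_noise_scaling_in_linear_regime(self, setup):
        _, sc, mye, grad, params = setup
        W, I, _ = regional_params(mye, grad, params)
        variances = []
        sigmas = (0.001, 0.002, 0.004)
        for s in sigmas:
            sim = simulate_mfm(sc, W, I, s, params.G, duration=120.0, seed=3)
            variances.append(sim.S_trace[4000:].var(axis=0).mean())
        slope = np.polyfit(np.log(sigmas), 0.5 * np.log(variances), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_large_dt_rejected(self, setup):
        _, sc, mye, grad, params = setup
        W, I, _ = regional_params(mye, grad, params)
        with pytest.raises(InvalidArgumentError):
            simulate_mfm(sc, W, I, 0.0, params.G, dt=0.05, duration=10.0)


class TestHemodynamics:
    def test_constant_gating_constant_bold(self):
        S = np.full((20000, 3), 0.2)
        bold = hemodynamics(S, 0.01, TR=2.0, burn_in=60.0)
        assert np.ptp(bold, axis=0).max() < 1e-8

    def test_output_length(self):
        S = np.full((30000, 2), 0.1)  # 300 s at dt=0.01
        bold = hemodynamics(S, 0.01, TR=2.0, burn_in=20.0)
        assert bold.shape == (140, 2)

    def test_monotone_amplitude_response(self):
        """A stronger gating step produces a larger BOLD excursion."""
        base = np.full((12000, 1), 0.05)
        excursions = []
        for amp in (0.1, 0.2):
            S = base.copy()
            S[6000:, 0] = 0.05 + amp
            bold = hemodynamics(S, 0.01, TR=2.0, burn_in=20.0)
            excursions.append(np.ptp(bold))
        assert excursions[1] > excursions[0]

    def test_tr_not_multiple_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hemodynamics(np.zeros((100, 1)), 0.03, TR=2.0)


class TestFCD:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        bold = rng.normal(size=(80, 6)) + np.sin(
            np.arange(80) / 5
        )[:, None] * rng.normal(size=6)
        F = fcd(bold, window=15, stride=5)
        assert np.allclose(F, F.T)
        assert np.allclose(np.diag(F), 1.0)

    def test_iid_signals_low_off_diagonal(self):
        rng = np.random.default_rng(1)
        F = fcd(rng.normal(size=(200, 10)), window=20, stride=5)
        off = F[np.triu_indices(F.shape[0], 1)]
        assert np.abs(off).mean() < 0.25

    def test_periodic_signal_high_bands(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(20, 6))
        bold = np.tile(block, (6, 1)) + rng.normal(0, 0.01, (120, 6))
        F = fcd(bold, window=20, stride=20)
        off = F[np.triu_indices(F.shape[0], 1)]
        assert off.min() > 0.9


class TestFitCost:
    def test_identical_inputs_zero(self):
        rng = np.random.default_rng(3)
        fc = np.corrcoef(rng.normal(size=(50, 8)).T)
        F = np.corrcoef(rng.normal(size=(10, 5)))
        out = fit_cost(fc, fc, F, F)
        assert out["cost"] == pytest.approx(0.0, abs=1e-12)

    def test_anti_correlated_fc_term_two(self):
        rng = np.random.default_rng(4)
        fc = np.corrcoef(rng.normal(size=(50, 8)).T)
        out = fit_cost(-fc, fc)
        assert out["fc_term"] == pytest.approx(2.0)

    def test_ks_matches_brute_force(self):
        from synfac.dynamics import _ks_distance

        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(1.0, 1.0, 20)
        pooled = np.concatenate([a, b])
        gap = max(abs((a <= t).mean() - (b <= t).mean()) for t in pooled)
        assert _ks_distance(a, b) == pytest.approx(gap, abs=1e-12)


class TestCMAES:
    def test_sphere_minimized(self):
        res = cma_es(lambda x: float(np.sum((x - 1.2) ** 2)),
                     np.zeros(5), 0.5, max_generations=80, seed=0)
        assert res.f_best < 1e-6

    def test_zero_generations_returns_initial(self):
        x0 = np.array([0.3, 0.7])
        res = cma_es(lambda x: float(np.sum(x**2)), x0, 0.5,
                     max_generations=0, seed=0)
        assert np.allclose(res.x_best, x0)
        assert res.f_best == pytest.approx(np.sum(x0**2))

    def test_bounds_respected(self):
        bounds = np.array([[0.0, 1.0]] * 3)
        res = cma_es(lambda x: float(np.sum((x + 2) ** 2)), np.full(3, 0.5),
                     0.4, bounds=bounds, max_generations=40, seed=1)
        assert np.all(res.x_best >= 0.0)

    def test_deterministic_given_seed(self):
        f = lambda x: float(np.sum(x**2) + np.sin(x[0]))
        a = cma_es(f, np.ones(3), 0.3, max_generations=20, seed=5)
        b = cma_es(f, np.ones(3), 0.3, max_generations=20, seed=5)
        assert np.array_equal(a.x_best, b.x_best)


class TestParamDiffFactorCorr:
    def test_planted_difference_recovers_correlation(self, setup):
        parc, sc, mye, grad, _ = setup
        dist = parc.distance_matrix()
        rng = np.random.default_rng(6)
        kern = np.exp(-dist / 30)
        fmaps = (kern @ rng.normal(size=(20, 3))).T
        W_nc = np.full(20, 0.5)
        W_scz = W_nc + 0.1 * fmaps[2]  # planted difference = factor-3 map
        I = np.full(20, 0.3)
        table = param_diff_factor_corr(
            {"W": W_scz, "I": I}, {"W": W_nc, "I": I}, fmaps, dist,
            n_surrogates=50, seed=0,
        )
        row = table[(table.parameter == "W") & (table.factor == 2)].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-10)
        flagged = table[table.parameter == "I"]
        assert (flagged.flag == "constant-difference").all()
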