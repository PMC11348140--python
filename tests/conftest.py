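import numpy as np
import pytest

from synfac.infodynamics import pairwise_interaction_matrices
from synfac.synthdata import make_parcellation, simulate_cohort


def random_lagged_cov(rng, strength=0.6):
    """Random valid 4x4 lagged covariance: sample cov of a short VAR path."""
    A = rng.normal(0, strength / 2, (2, 2))
    A = A / max(1.0, 1.1 * np.max(np.abs(np.linalg.eigvals(A))))
    x = np.zeros(2)
    xs = []
    for _ in range(400):
        x = A @ x + rng.normal(size=2)
        xs.append(x.copy())
    xs = np.array(xs)
    stacked = np.column_stack([xs[:-1], xs[1:]])
    return np.cov(stacked.T, ddof=1)


@pytest.fixture(scope="session")
def small_parcellation():
    return make_parcellation(18, 4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_parcellation):
    """A compact planted cohort shared by several tests."""
    cohort, series, truth = simulate_cohort(
        small_parcellation, n_nc=14, n_scz=14, T=160, K=3, effect=0.6, seed=3
    )
    return cohort, series, truth


@pytest.fixture(scope="session")
def small_synergy(small_cohort):
    cohort, series, _ = small_cohort
    mats = {}
    for ts in series:
        syn, red = pairwise_interaction_matrices(ts)
        mats[ts.subject_id] = (syn, red)
    return mats
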