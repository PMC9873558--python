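import numpy as np
import pandas as pd
import pytest

from pharmacotyping import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient cohort shared by tests that only read from it."""
    return simulate_cohort(SimulationConfig(n_patients=150), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def mvn_missing():
    """200 x 8 equicorrelated Gaussian matrix with 30% MCAR missingness."""
    def _make(seed, n=200, p=8, rho=0.6, miss=0.3):
        g = np.random.default_rng(seed)
        cov = np.full((p, p), rho)
        np.fill_diagonal(cov, 1.0)
        X = g.multivariate_normal(np.zeros(p), cov, n)
        mask = g.random((n, p)) < miss
        df = pd.DataFrame(np.where(mask, np.nan, X),
                          columns=[f"c{i}" for i in range(p)])
        return df, X, mask
    return _make
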