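import numpy as np
import pytest

import kinenet as kn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_exp_dataset():
    """Noise-free two-exponential data at three wavelengths."""
    times = kn.log_time_grid(1e-2, 1e2, 9)
    wavelengths = np.array([500.0, 550.0, 600.0])
    taus = np.array([0.5, 20.0])
    dads = np.array([[1.0, 0.6, 0.2], [-0.3, 0.8, 1.0]])
    signal = kn.compose_signal(taus, dads, times)
    ds = kn.KineticDataset(times, wavelengths, signal)
    return ds, taus, dads


def random_rate_matrix(rng, n=3):
    """Random valid dissipative rate matrix with nonneg off-diagonals."""
    K = rng.uniform(0.1, 2.0, size=(n, n))
    np.fill_diagonal(K, 0.0)
    exit_rates = rng.uniform(0.0, 0.5, size=n)
    for j in range(n):
        K[j, j] = -(K[:, j].sum() + exit_rates[j])
    c0 = rng.uniform(0.0, 1.0, size=n)
    return kn.RateMatrix(K=K, c0=c0)
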