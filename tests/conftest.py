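import numpy as np
import pytest

from specfuse.synth import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def coarse_config():
    """Small, fast two-condition study: 10 nm sampling, modest n."""
    return SyntheticConfig(n_samples=60, grid_step=10.0, seed=7)


def planted_problem(n=60, p=30, true_vars=(3, 11, 22),
                    coefs=(1.0, 0.8, 0.6), noise_sd=0.1, seed=0):
    """Linear regression with a few informative columns among noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[list(true_vars)] = coefs
    y = X @ beta + rng.normal(0.0, noise_sd, n)
    return X, y, np.array(true_vars)
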