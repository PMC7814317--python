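import numpy as np
import pytest

import neurodegree as nd


@pytest.fixture(scope="session")
def small_cohort():
    """A 10+10 cohort in degrees mode with a clear group effect."""
    return nd.generate_cohort(n_hc=10, n_amci=10, delta_beta=0.1,
                              cognition_slope=20.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric_r(rng, n):
    """A random symmetric correlation-like matrix with zero diagonal."""
    a = rng.uniform(-1, 1, size=(n, n))
    r = (a + a.T) / 2
    np.fill_diagonal(r, 0.0)
    return r
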