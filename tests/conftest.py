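import numpy as np
import pytest

import lagte


@pytest.fixture(scope="session")
def ar_pair():
    """One default coupled-AR realization (N = 300)."""
    return lagte.simulate_coupled_ar(seed=1)


@pytest.fixture(scope="session")
def null_pair():
    """One pair of independent standard-normal series (N = 300)."""
    return lagte.simulate_null_pair(300, seed=1)


@pytest.fixture(scope="session")
def linear_pair():
    """y_n = 0.5 x_{n-1} + v_n with unit-variance white noises, n = 10000."""
    rng = np.random.default_rng(42)
    n = 10000
    x = rng.standard_normal(n)
    v = rng.standard_normal(n)
    y = np.empty(n)
    y[0] = v[0]
    y[1:] = 0.5 * x[:-1] + v[1:]
    return lagte.BivariateSeries(x, y)
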