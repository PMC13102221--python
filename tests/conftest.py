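import numpy as np
import pytest

from gmolesta import (
    ClimateSpec,
    TABLE1_PARAMS,
    accumulate_cdd,
    gen_temperature,
)


@pytest.fixture(scope="session")
def table1():
    return TABLE1_PARAMS


@pytest.fixture(scope="session")
def quiet_year_temps():
    """A noise-free synthetic year: deterministic, smooth annual cycle."""
    return gen_temperature(ClimateSpec(noise_sd=0.0, seed=0), year=2023)


@pytest.fixture(scope="session")
def quiet_year_cdd(quiet_year_temps):
    return accumulate_cdd(quiet_year_temps)


def sine_dd_oracle(tmin, tmax, lower=8.1, upper=32.2, n_steps=100_000):
    """Trapezoid integration of the clipped daily sine: the independent
    degree-day oracle the closed form must match."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_steps + 1)
    m = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    t = m + amp * np.sin(theta)
    integrand = np.clip(np.minimum(t, upper) - lower, 0.0, None)
    return np.trapezoid(integrand, theta) / (2.0 * np.pi)
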