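import numpy as np
import pytest

from ccmnet import (
    MonthlySeries,
    simulate_coupled_logistic,
    two_species_spec,
)


@pytest.fixture(scope="session")
def chaotic_pair():
    """A unidirectionally coupled chaotic pair (X forces Y), n = 400."""
    data, truth = simulate_coupled_logistic(
        two_species_spec(beta_yx=0.1, process_noise_sd=0.005), 400, seed=7
    )
    return data["X"].to_numpy(), data["Y"].to_numpy(), truth


@pytest.fixture()
def monthly(rng=None):
    """A 40-year monthly series with trend, seasonality and anomaly."""
    rng = np.random.default_rng(11)
    n = 480
    t = np.arange(n)
    month = t % 12 + 1
    values = 5.0 + 0.01 * t + 1.5 * np.sin(2 * np.pi * month / 12) + rng.normal(0, 1, n)
    return MonthlySeries("s1", "v", (1980, 1), values)
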