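import numpy as np
import pandas as pd
import pytest

from shorewhale import SimConfig, simulate_scenario


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, duration_h=3.0, n_whales=2)


@pytest.fixture(scope="session")
def scenario(small_config):
    """One small simulated study shared across tests (read-only)."""
    return simulate_scenario(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150601)


def random_resampled_track(rng, n_steps=7, step_m=150.0):
    """A random 90-s resampled track DataFrame with n_steps steps."""
    heads = np.cumsum(rng.normal(0, 0.8, n_steps))
    steps = rng.gamma(4.0, step_m / 4.0, n_steps)
    dx = steps * np.sin(heads)
    dy = steps * np.cos(heads)
    return pd.DataFrame({
        "t_s": 90.0 * np.arange(n_steps + 1),
        "x_m": np.concatenate([[0.0], np.cumsum(dx)]),
        "y_m": np.concatenate([[0.0], np.cumsum(dy)]),
    })
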