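import logging

import numpy as np
import pytest

from oddball.simulate import SimConfig, simulate_session

logging.getLogger("oddball").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """A small but complete simulated session with spike times."""
    config = SimConfig(n_neurons=6, tuning_reps=8, min_oddballs=12, seed=7)
    return simulate_session(config)


@pytest.fixture(scope="session")
def medium_responses():
    """Count-level responses for a mid-sized population (fast path)."""
    config = SimConfig(n_neurons=30, tuning_reps=20, min_oddballs=30, seed=11)
    return simulate_session(config, spike_times=False, motion=False).responses
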