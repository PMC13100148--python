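import numpy as np
import pytest

import spiketau as st


@pytest.fixture(scope="session")
def small_table():
    """12-neuron two-condition experiment with default trial structure."""
    cfg = st.small_config(n_neurons_short=6, n_neurons_long=6, seed=42)
    table, truth = st.simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def mid_table():
    """60-neuron two-condition experiment for end-to-end directional checks."""
    cfg = st.SimConfig(n_neurons_short=30, n_neurons_long=30, seed=11)
    table, truth = st.simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
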