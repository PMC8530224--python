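import numpy as np
import pytest

from scanagree.synthetic import SimulationConfig, simulate_volume_table


@pytest.fixture(scope="session")
def default_table():
    """One simulated study table under the default (study-like) conditions."""
    return simulate_volume_table(SimulationConfig(seed=7))


@pytest.fixture
def noise_free_config():
    """No scan-rescan noise, no scanner bias: every replicate is identical."""
    return SimulationConfig(
        n_subjects=5,
        scanners=("a", "b", "c"),
        structures=[("s1", 100.0, 10.0), ("s2", 10.0, 1.0)],
        scanner_bias={},
        residual_cv_percent=0.0,
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
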