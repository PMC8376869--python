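import numpy as np
import pytest

from hybridmhc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_individuals={"bream": 40, "roach": 40, "hybrid": 30},
        pool_sizes={("bream", "DAB1"): 4, ("bream", "DAB3"): 10,
                    ("roach", "DAB1"): 6, ("roach", "DAB3"): 14},
        read_depth=200,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
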