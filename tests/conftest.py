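import numpy as np
import pytest

from stcap.simulate import SimConfig, simulate_cap_genome


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale genome: 4 arms, short flanks, ~40-70 kbp caps."""
    return SimConfig(seed=11, n_arms=4, arrays_per_cap=(6, 8),
                     blocks_per_array=(2, 3), flank_length=20_000,
                     boundary_width=5_000)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_cap_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
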