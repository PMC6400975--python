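import numpy as np
import pytest

from lexigrow import SimConfig


@pytest.fixture(scope="session")
def cfg():
    """Full-scale configuration (25x25 areas)."""
    return SimConfig()


@pytest.fixture(scope="session")
def tiny_cfg():
    """A 5x5-cell toy area for dense-oracle comparisons."""
    return SimConfig(grid_size=5, neighbourhood=3, inhib_neighbourhood=3,
                     pattern_size=3, sigma=2.0, dt=0.5)


@pytest.fixture(scope="session")
def scaled_cfg():
    """Desk-scale study preset."""
    return SimConfig.scaled()
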