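import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from wormsleep import SyntheticConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def square_wave_worm():
    """One worm with fixed 5-min sleep / 5-min motion bouts through a 1-h
    lethargus, sampled every 5 s."""
    cfg = SyntheticConfig(seed=7, duration_s=5400.0, lethargus=(600.0, 4200.0),
                          bout_distribution="fixed", sleep_bout_mean_s=300.0,
                          motion_bout_mean_s=300.0)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def default_worm():
    cfg = SyntheticConfig(seed=11, duration_s=5400.0, lethargus=(600.0, 4200.0))
    return generate_recording(cfg)
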