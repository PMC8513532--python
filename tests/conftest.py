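import warnings

import numpy as np
import pytest

from hyperflow.config import SimConfig
from hyperflow.synth import simulate_study

# mne chatters about epoch lengths; the suite checks outputs, not logs
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Shortened study (2 pairs x 1 song) with the default injected effects."""
    return SimConfig(
        n_pairs=2,
        n_songs=1,
        rest_duration=6.0,
        play_duration=20.0,
        emit_sensors=True,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    study, truth = simulate_study(tiny_config)
    return study, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
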