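import numpy as np
import pytest

from avwm.config import Config
from avwm.architecture import build_network
from avwm import stimuli


@pytest.fixture()
def config():
    return Config()


@pytest.fixture()
def quiet_config():
    """Noise-free configuration for deterministic dynamical checks."""
    cfg = Config()
    cfg.noise_amplitude = 0.0
    return cfg


@pytest.fixture()
def quiet_network(quiet_config):
    return build_network(quiet_config)


@pytest.fixture()
def network(config):
    return build_network(config)


@pytest.fixture(scope="session")
def contours():
    return stimuli.stimulus_library(8, "a", seed=17)


@pytest.fixture(scope="session")
def shapes():
    return stimuli.stimulus_library(8, "v", seed=23)
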