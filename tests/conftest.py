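import numpy as np
import pytest

import posturesim as ps


@pytest.fixture(scope="session")
def model_config():
    return ps.ModelConfig()


@pytest.fixture(scope="session")
def pm(model_config):
    """Packed default model (session-scoped so numba compiles once)."""
    return ps.pack_model(model_config)


@pytest.fixture(scope="session")
def standing_guess(pm):
    """Heuristic controller that stands in the ankle-strategy variant."""
    return ps.initial_guess(pm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
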