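import numpy as np
import pytest

from eegdcm import synthetic_data as sd


@pytest.fixture(scope="session")
def small_session():
    """A short 4-block session shared by read-only tests."""
    cfg = sd.SimulationConfig(n_blocks=4, fs_raw=512.0, n_distractors=8)
    return sd.simulate_session(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
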