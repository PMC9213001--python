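import numpy as np
import pytest

from revadapt.cochlea import CochlearConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_coch_cfg():
    """Reduced cochlear configuration for fast audio-level tests."""
    return CochlearConfig(f_min=300.0, f_max=6500.0, n_channels=12)


@pytest.fixture(scope="session")
def small_fs():
    return 16000.0
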