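import numpy as np
import pytest

from polarsmolm.optics import OpticalConfig, basis_psfs


@pytest.fixture(scope="session")
def cfg():
    """Default optical configuration (shared so the basis cache is reused)."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def bset(cfg):
    return basis_psfs(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
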