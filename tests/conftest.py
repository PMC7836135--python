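import numpy as np
import pytest

from ssvepmod.csd import build_kernel
from ssvepmod.montage import make_montage


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def kernel(montage):
    return build_kernel(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
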