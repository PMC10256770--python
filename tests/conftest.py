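import numpy as np
import pytest

from cryobank.protocol import vmp_loading_protocol, vmp_unloading_protocol


@pytest.fixture(scope="session")
def loading_protocol():
    return vmp_loading_protocol()


@pytest.fixture(scope="session")
def unloading_protocol():
    return vmp_unloading_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
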