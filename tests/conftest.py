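import numpy as np
import pytest

from activedrop import DEFAULT_PARAMETERS, TissueParameters


@pytest.fixture
def params() -> TissueParameters:
    return DEFAULT_PARAMETERS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7321)
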