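import numpy as np
import pytest

from memsnn import DeviceParams, EncoderParams, LIFParams, PlasticityParams


@pytest.fixture
def linear_device() -> DeviceParams:
    return DeviceParams(nu_ltp=0.0, nu_ltd=0.0)


@pytest.fixture
def encoder() -> EncoderParams:
    return EncoderParams()


@pytest.fixture
def lif() -> LIFParams:
    return LIFParams()


@pytest.fixture
def plasticity() -> PlasticityParams:
    return PlasticityParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
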