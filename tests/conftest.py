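import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_neuron():
    from lifnet.core import NeuronParameters

    return NeuronParameters()


@pytest.fixture
def clamp():
    from lifnet.core import ClampPolicy

    return ClampPolicy()


@pytest.fixture
def no_clamp():
    from lifnet.core import ClampPolicy

    return ClampPolicy(enabled=False)
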