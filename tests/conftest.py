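import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def normal_epoch():
    from epidisc import gen_epoch

    return gen_epoch("normal", seed=101)


@pytest.fixture(scope="session")
def spike_epoch():
    from epidisc import gen_epoch

    return gen_epoch("spike", seed=202)
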