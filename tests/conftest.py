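import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["glycolysis", "oxidative_tca", "reductive_branch",
                        "bifurcated_tca", "ppp_shunt"])
def preset_name(request):
    return request.param
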