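import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    from crmkit.simulate import make_genome

    return make_genome(30_000, 0.42, seed=7)


@pytest.fixture
def test_pwms():
    from crmkit.simulate import gli_like_pwm, hox13_like_pwm

    return [gli_like_pwm(), hox13_like_pwm()]
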