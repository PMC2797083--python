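import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from syncnoise.models import fitzhugh_nagumo, hindmarsh_rose
from syncnoise.simulate import SimConfig, simulate_noise_free

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fn_model():
    return fitzhugh_nagumo()


@pytest.fixture(scope="session")
def hr_model():
    return hindmarsh_rose()


@pytest.fixture(scope="session")
def fn_limit_cycle_point(fn_model):
    """A state on (numerically: very near) the noise-free FN limit cycle."""
    warm = simulate_noise_free(
        fn_model, None, np.array([0.0, 0.0]), SimConfig(dt=0.002, t_end=120.0, seed=0)
    )
    return warm.states[-1, 0].copy()


@pytest.fixture(scope="session")
def fn_reference(fn_model, fn_limit_cycle_point):
    """Noise-free FN trajectory starting on the limit cycle (dt = 2 ms)."""
    return simulate_noise_free(
        fn_model, None, fn_limit_cycle_point, SimConfig(dt=0.002, t_end=80.0, seed=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
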