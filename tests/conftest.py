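import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_params():
    from fgmcohorts import ModelParams

    return ModelParams(
        n=3, m=2, sigma2=0.004, U=0.01, N=200, w0=0.5,
        generations=300, record_every=10, seed=11, placement="axis",
    )
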