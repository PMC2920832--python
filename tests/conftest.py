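import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pseudowalk import PseudopodParams, strain_params

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wt5h() -> PseudopodParams:
    """Starved wild-type parameter set (high splitting fraction)."""
    return strain_params("WT 5h")


@pytest.fixture(scope="session")
def wt1h() -> PseudopodParams:
    """Fed wild-type parameter set (low splitting fraction)."""
    return strain_params("WT 1h")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
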