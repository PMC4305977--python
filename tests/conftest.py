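import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppcount.params import PixelClassParams, default_params

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> PixelClassParams:
    """The shipped default DAB threshold set."""
    return default_params()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)
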