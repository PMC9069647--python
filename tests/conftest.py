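import random

import pytest
from hypothesis import HealthCheck, settings

from crossbeta.geometry import GeometryParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params():
    return GeometryParams()


@pytest.fixture
def rng():
    return random.Random(20210726)
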