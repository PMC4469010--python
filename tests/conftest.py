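import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    """A deterministic 32x32 phantom with one gray circle, one full-tone
    triangle and one full-tone circle on a black background."""
    from ctbrush.phantom import Shape, make_phantom
    from ctbrush.raygeom import GridDims

    return make_phantom(
        GridDims(32, 32),
        [Shape("circle", 10, 10, 5, True),
         Shape("triangle", 20, 18, 8, False),
         Shape("circle", 24, 7, 4, False)],
        inverted=False,
    )
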