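import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dsacolor.phantom import BreakpointSpec, PhantomSpec, generate_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# a 64x64 phantom small enough for per-pixel fitting in tests
SMALL_PATH = ((50.0, 8.0), (22.0, 26.0), (32.0, 56.0))


def small_spec(**overrides) -> PhantomSpec:
    kw = dict(
        height=64,
        width=64,
        n_frames=36,
        tube_path=SMALL_PATH,
        tube_radius_px=2.5,
        breakpoint=BreakpointSpec(leak_radius_px=4.5),
        seed=0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless 64x64 phantom with a breakpoint."""
    return generate_phantom(small_spec(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry at the default noise level."""
    return generate_phantom(small_spec())
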