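import numpy as np
import pytest

from kscrub.motion import make_motion_track, make_sampling_order, simulate_kspace
from kscrub.phantoms import make_phantom


@pytest.fixture(scope="session")
def shepp256():
    return make_phantom(256, 256, "shepp_logan", seed=0)


@pytest.fixture(scope="session")
def ellipses64():
    return make_phantom(64, 64, "random_ellipses", seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def simulate_small(seed: int, start_fraction: float = 0.35, size: int = 64):
    """A small corrupted acquisition for fast tests."""
    phantom = make_phantom(size, size, "random_ellipses", seed=seed)
    order = make_sampling_order(size, seed=seed + 1)
    track = make_motion_track(size, start_fraction, seed=seed + 2)
    return simulate_kspace(phantom, order, track, seed=seed)
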