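"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """A smooth random 2D image in [0, 1], 64x64."""
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.random((64, 64)), 2.0)
    img -= img.min()
    return img / img.max()


@pytest.fixture
def random_volume(rng):
    """A smooth random 3D volume in [0, 1], 32x32x32."""
    from scipy.ndimage import gaussian_filter

    vol = gaussian_filter(rng.random((32, 32, 32)), 2.0)
    vol -= vol.min()
    return vol / vol.max()
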