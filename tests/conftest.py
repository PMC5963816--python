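import math

import numpy as np
import pytest
from hypothesis import settings

from gradorder import (IntensityImage, LightConfig, NormalField,
                       heightfield_to_normals, make_bandpass_heightfield,
                       make_bumpy_sphere_normals)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def frontal_light():
    return LightConfig(0.0, 0.0, math.pi)


@pytest.fixture
def flat_normals():
    """An 8x8 patch facing the camera."""
    n = np.tile(np.array([0.0, 0.0, 1.0]), (8, 8, 1))
    return NormalField(n, np.ones((8, 8), dtype=bool))


@pytest.fixture(scope="session")
def bumpy_sphere():
    return make_bumpy_sphere_normals(64, bump_amplitude=0.3, seed=3)


@pytest.fixture(scope="session")
def bandpass_geometries():
    """Three small band-pass surfaces for correlation tests."""
    return [heightfield_to_normals(make_bandpass_heightfield(64, 6.0, 0.5, 3.0, seed=s))
            for s in (11, 12, 13)]


@pytest.fixture
def ramp_image():
    """Intensity ramp increasing rightward (gradient direction 0)."""
    v = np.tile(np.linspace(0.1, 0.9, 32), (32, 1))
    return IntensityImage(v, np.ones((32, 32), dtype=bool))
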