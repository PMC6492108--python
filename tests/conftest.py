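import numpy as np
import pytest

import epiunwarp as eu


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_geometry():
    """24 x 20 grid, full Fourier — cheap enough for dense oracles."""
    return eu.GridGeometry.from_bandwidth(24, 20, bw_per_pixel_hz=10.4)


@pytest.fixture(scope="session")
def small_scene():
    """32 x 32 scene with 3 coils for fast end-to-end tests."""
    geometry = eu.GridGeometry.from_bandwidth(
        32, 32, bw_per_pixel_hz=10.4, partial_fourier=0.75
    )
    return eu.make_scene(geometry, peak_hz=120.0, n_coils=3, seed=7)


def random_field(geometry, rng, scale_hz=50.0):
    return eu.B0Map(delta_b0_hz=rng.normal(0.0, scale_hz, geometry.shape))


def random_image(geometry, rng):
    return rng.normal(size=geometry.shape) + 1j * rng.normal(size=geometry.shape)
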