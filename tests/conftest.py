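import numpy as np
import pytest

from hyperyield.datacube import SpectralCube
from hyperyield.synthetic_scene import SceneParams, make_field_scene


@pytest.fixture(scope="session")
def small_scene():
    """A reduced 61-band scene shared by read-only tests."""
    params = SceneParams(
        n_bands=61, subplot_shape_px=(16, 60), gsd=0.25, seed=7
    )
    return make_field_scene(params)


@pytest.fixture
def random_cube():
    """Factory for small random radiance cubes."""

    def _make(n_bands=5, rows=4, cols=4, seed=0, domain="radiance", gsd=0.5):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 2.0, (n_bands, rows, cols))
        wavelengths = np.linspace(500.0, 900.0, n_bands)
        return SpectralCube(values, wavelengths, domain, gsd)

    return _make
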