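import numpy as np
import pytest
from hypothesis import settings

from octlayers.instruments import InstrumentConfig
from octlayers.phantom import LayerGeometry

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_config() -> InstrumentConfig:
    """A small UHR-like grid so phantom tests run in milliseconds.

    0.7 mm air depth over 192 rows gives 2.64 µm/px axially — the full
    292 µm retina fits with margin — and 1.6 mm of scan over 160 columns.
    """
    return InstrumentConfig(
        name="mini",
        axial_resolution_um=5.0,
        depth_pixels=192,
        width_pixels=160,
        scan_width_mm=1.6,
        scan_depth_air_mm=0.7,
    )


@pytest.fixture(scope="session")
def mini_geometry() -> LayerGeometry:
    """Pit narrowed to fit the 1.6 mm mini scan."""
    return LayerGeometry(pit_fwhm_mm=0.5, curvature_um=10.0, undulation_um=2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
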