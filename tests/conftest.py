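import numpy as np
import pytest
from hypothesis import settings

from myoaniso import Ellipse, PhantomParams, WallGeometry, default_geometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def circle_geometry() -> WallGeometry:
    """Concentric circles: centre (200, 200), endo radius 80 px, epi 120 px."""
    return WallGeometry(
        endo=Ellipse(200, 200, 80, 80),
        epi=Ellipse(200, 200, 120, 120),
    )


@pytest.fixture
def small_params() -> PhantomParams:
    """160x160-px phantom at 25 um/px (10x10-px ROIs), noiseless."""
    return PhantomParams(speckle_model="none", image_size_px=(160, 160), pixel_size_um=25.0)


@pytest.fixture
def small_speckled_params() -> PhantomParams:
    return PhantomParams(
        speckle_model="exponential", image_size_px=(160, 160), pixel_size_um=25.0, seed=0
    )


@pytest.fixture
def small_geometry(small_params) -> WallGeometry:
    return default_geometry(small_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
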