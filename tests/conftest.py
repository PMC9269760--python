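import numpy as np
import pytest

from rseikit import data
from rseikit.aod import make_synthetic_lut
from rseikit.raster import RasterGrid
from rseikit.scene import SceneConfig, make_scene


@pytest.fixture(scope="session")
def published_lut():
    """Complete-grid lookup table whose nodes include the published HJ1-CCD
    sample rows exactly (red band), with the synthetic smooth model filling
    the remaining grid."""
    return make_synthetic_lut(
        theta_s=(0, 6, 24, 60),
        theta_v=(0, 3, 30, 60),
        phi=(0, 12, 24, 36, 48, 60, 72, 84, 96, 108, 120, 132, 144, 156, 168, 180),
        tau=(0.0001, 0.25, 1.5, 1.95),
        overrides=data.hj1_lut_sample_frame(),
    )


@pytest.fixture(scope="session")
def default_scene():
    return make_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def clean_scene(published_lut):
    """Noise-free scene, truth AOD snapped to the LUT tau grid, geometry at
    a published-row node: the exact-recovery setting."""
    cfg = SceneConfig(
        seed=11, noise_sd=0.0, snap_aod_to_grid=True, geometry=(24.0, 30.0, 96.0)
    )
    return make_scene(cfg, lut=published_lut)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_grid(values, **kw):
    return RasterGrid(np.asarray(values, dtype=float), **kw)
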