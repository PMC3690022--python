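import numpy as np
import pytest

from fibercount import CountingRules, SceneParams, TileGeometry


@pytest.fixture(scope="session")
def default_rules() -> CountingRules:
    return CountingRules()


@pytest.fixture(scope="session")
def small_geometry() -> TileGeometry:
    """A reduced-extent tile for cheap unit tests (same calibration)."""
    return TileGeometry(pixel_size=0.4, extent_um=(260.0, 196.0))


@pytest.fixture(scope="session")
def full_geometry() -> TileGeometry:
    """The full stage-step tile (650 x 490 um)."""
    return TileGeometry()


@pytest.fixture
def clean_scene() -> SceneParams:
    """Separated fibers, no artifacts, no noise."""
    return SceneParams(n_chrysotile=8, noise_sigma=0.0, seed=7)


def rasterize_ellipse(semi_major: float, semi_minor: float, pad: int = 10) -> np.ndarray:
    """Boolean mask of an axis-aligned solid ellipse (test helper)."""
    h = int(2 * semi_minor) + 2 * pad
    w = int(2 * semi_major) + 2 * pad
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) / semi_major) ** 2 + ((yy - cy) / semi_minor) ** 2 <= 1.0
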