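import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phasesnake import RectROI, SceneSpec, crop, make_cell_image

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def roi_around(spec: SceneSpec, margin: float = 8.0) -> RectROI:
    """Square ROI enclosing the cell plus halo with a margin."""
    cx, cy = spec.cell_center
    half = int(spec.max_radius + spec.halo_extent + margin)
    return RectROI(int(cy) - half, int(cx) - half, int(cy) + half + 1, int(cx) + half + 1)


@pytest.fixture(scope="session")
def scene():
    """Default rendered scene: (spec, full image, full ground-truth mask)."""
    spec = SceneSpec()
    img, mask = make_cell_image(spec)
    return spec, img, mask


@pytest.fixture(scope="session")
def scene_roi(scene):
    """Default scene cropped to its ROI: (spec, roi, roi image, roi mask)."""
    spec, img, mask = scene
    roi = roi_around(spec)
    return spec, roi, crop(img, roi), crop(mask.astype(float), roi) > 0.5


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
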