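import numpy as np
import pytest

from halfcontour.phantom import EchoSpec, ShapeSpec, make_shape_mask, render_phantom
from halfcontour.segmentation import Contour, TumorRegion, trace_contour


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def disk_mask():
    """Rasterized disk, radius 40, centered in a 256x256 frame."""
    spec = ShapeSpec(base_radius_px=40.0, center=(128.0, 128.0), rng_seed=0)
    return make_shape_mask(spec, (256, 256))


@pytest.fixture
def star_mask():
    """Spiculated star (a=0.3, 12 lobes) in a 256x256 frame."""
    spec = ShapeSpec(
        base_radius_px=40.0,
        spiculation_amplitude=0.3,
        spiculation_lobes=12,
        center=(128.0, 128.0),
        rng_seed=7,
    )
    return make_shape_mask(spec, (256, 256))


def contour_of(mask: np.ndarray) -> Contour:
    """Trace the boundary of a clean binary mask (no smoothing)."""
    region = TumorRegion(mask=(np.asarray(mask) > 0).astype(np.uint8), seed=(0, 0))
    return trace_contour(region)


@pytest.fixture
def disk_contour(disk_mask):
    return contour_of(disk_mask)


@pytest.fixture
def star_contour(star_mask):
    return contour_of(star_mask)


@pytest.fixture
def clean_phantom_image(disk_mask):
    """Noise-free rendering of the disk phantom."""
    return render_phantom(disk_mask, EchoSpec(speckle_scale=0.0), rng_seed=0)
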