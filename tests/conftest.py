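import numpy as np
import pytest
from shapely.geometry import Polygon

from rimquant.imaging_io import FluorescenceImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def flat_image():
    """64x64 image of constant value 3.5 with 1 mm pixels."""
    return FluorescenceImage(
        pixels=np.full((64, 64), 3.5), pixel_size_um=1000.0, channel="NIR"
    )


def random_convex_polygon(rng, frame=64, n_points=8):
    """A random simple (convex-hull) polygon inside a frame."""
    from scipy.spatial import ConvexHull

    pts = rng.uniform(0, frame, size=(n_points, 2))
    hull = ConvexHull(pts)
    return Polygon(pts[hull.vertices])


def random_mask(rng, shape, density=0.1, ensure_nonempty=True):
    m = rng.random(shape) < density
    if ensure_nonempty and not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m
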