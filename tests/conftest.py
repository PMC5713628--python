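import numpy as np
import pytest

from phenokit import imgcore


def make_star(tip_radius=50, notch_radius=14, n_points=5, size=110):
    """Rasterize an n-point star mask (tips up), returning (mask, tips)."""
    from skimage.draw import polygon

    c = size // 2
    tip_angles = -np.pi / 2 + 2 * np.pi * np.arange(n_points) / n_points
    verts = []
    tips = []
    for t in tip_angles:
        tips.append((c + tip_radius * np.cos(t), c + tip_radius * np.sin(t)))
        verts.append(tips[-1])
        n_ = t + np.pi / n_points
        verts.append((c + notch_radius * np.cos(n_), c + notch_radius * np.sin(n_)))
    verts = np.array(verts)
    mask = np.zeros((size, size), np.uint8)
    rr, cc = polygon(verts[:, 1], verts[:, 0], shape=(size, size))
    mask[rr, cc] = 255
    return mask, np.array(tips)


def make_disk(radius, size=None, center=None):
    from skimage.draw import disk as _disk

    size = size or (2 * radius + 10)
    center = center or (size // 2, size // 2)
    mask = np.zeros((size, size), np.uint8)
    rr, cc = _disk(center, radius, shape=(size, size))
    mask[rr, cc] = 255
    return mask


def single_contour(mask):
    contours = imgcore.find_objects(np.zeros(mask.shape, np.uint8), mask)
    assert len(contours) == 1
    return contours[0]


@pytest.fixture
def square_mask():
    m = np.zeros((60, 60), np.uint8)
    m[10:50, 10:50] = 255
    return m


@pytest.fixture
def star_mask():
    return make_star()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
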