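import numpy as np
import pytest

from orgquant.images import IntensityImage
from orgquant.segmentation import CellContour


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disk_mask(shape, center, radius):
    """Boolean disk: pixel centers within radius of center (x, y)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def make_circle_contour(center, radius, n_vertices=256):
    th = np.linspace(0.0, 2 * np.pi, n_vertices + 1)[:-1]
    return CellContour(
        np.column_stack(
            [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
        )
    )


def make_disk_image(shape, center, radius, value=1.0):
    img = np.zeros(shape)
    img[make_disk_mask(shape, center, radius)] = value
    return IntensityImage(img)


def random_blob_mask(rng, shape=(50, 50), n_seeds=4, n_grow=400):
    """Random connected blob grown from seed points; always hole-filled."""
    from scipy import ndimage as ndi

    mask = np.zeros(shape, dtype=bool)
    r0 = rng.integers(shape[0] // 4, 3 * shape[0] // 4)
    c0 = rng.integers(shape[1] // 4, 3 * shape[1] // 4)
    mask[r0, c0] = True
    for _ in range(n_grow):
        grown = ndi.binary_dilation(mask)
        frontier = np.argwhere(grown & ~mask)
        if len(frontier) == 0:
            break
        pick = frontier[rng.integers(len(frontier))]
        mask[pick[0], pick[1]] = True
    mask = ndi.binary_fill_holes(mask)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    return mask
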