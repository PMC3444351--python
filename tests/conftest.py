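import numpy as np
import pytest
from scipy import ndimage as ndi

from rootarch.segmentation import BinaryMask
from rootarch.synthetic import fixture_catalog, make_phantom


@pytest.fixture(scope="session")
def clean_phantoms():
    """The standard clean fixture suite: (spec, image, gt mask, known traits)."""
    out = []
    for spec in fixture_catalog(seed=7):
        img, gt, known = make_phantom(spec)
        out.append((spec, img, gt, known))
    return out


def random_blob_mask(rng: np.random.Generator, shape=(48, 48), quantile=0.72):
    """A single-component random blob mask with a background margin.

    Single 8-connected component implies every row of the vertical
    extent is nonempty (diagonal steps change the row by at most 1), so
    the bushiness traits are always defined.  The margin keeps distance
    transforms independent of the canvas placement.
    """
    inner = (shape[0] - 4, shape[1] - 4)
    field = ndi.gaussian_filter(rng.normal(size=inner), 3.0)
    mask = field > np.quantile(field, quantile)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return random_blob_mask(rng, shape, quantile - 0.05)
    sizes = np.bincount(labels.ravel())[1:]
    blob = labels == (int(np.argmax(sizes)) + 1)
    return BinaryMask(np.pad(blob, 2))


def random_multiblob_mask(rng: np.random.Generator, shape=(64, 64), quantile=0.75):
    """A possibly multi-component, possibly holed random mask (with margin)."""
    inner = (shape[0] - 4, shape[1] - 4)
    field = ndi.gaussian_filter(rng.normal(size=inner), 2.0)
    mask = field > np.quantile(field, quantile)
    if not mask.any():
        mask[inner[0] // 2, inner[1] // 2] = True
    return BinaryMask(np.pad(mask, 2))
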