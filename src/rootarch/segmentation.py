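"""Root/background segmentation by thresholding.

Three thresholding algorithms are provided, reflecting the common
observation that no single scheme suits every imaging setup:

``global``
    Foreground iff intensity is strictly above a fixed threshold value.
``adaptive``
    Foreground iff intensity strictly exceeds the mean over the
    ``block_size`` x ``block_size`` window centred on the pixel plus a
    (possibly negative) ``mean_shift`` offset.  Windows are truncated at
    the image border rather than padded, so no intensities are invented.
``double_adaptive``
    Foreground iff the mean intensity over squares grown around the
    pixel (sides 3, 5, ... up to ``neighborhood_size``) drops by at
    least ``bound_drop`` below the pixel's own intensity before the
    square reaches the critical size.  Bright pixels embedded in a
    bright region wider than the neighborhood never see the drop, which
    is why this algorithm tends to omit dense root clusters.

All algorithms finish by removing 8-connected foreground components
smaller than ``min_component_size`` pixels.  A single
``invert_polarity`` flag handles dark-roots-on-light-background images:
the image is intensity-inverted (global: the comparison is reversed)
before the standard rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, ParameterError
from .raster_io import GrayImage

__all__ = [
    "ALGORITHMS",
    "SegmentationParams",
    "BinaryMask",
    "ComponentLabeling",
    "label_components",
    "filter_small_components",
    "segment_global",
    "segment_adaptive",
    "segment_double_adaptive",
    "segment",
]

ALGORITHMS = ("global", "adaptive", "double_adaptive")

#: 8-connectivity structuring element used for component labeling.
STRUCTURE_8 = np.ones((3, 3), dtype=int)


@dataclass
class BinaryMask:
    """Boolean foreground mask with the source image's scale attached."""

    pixels: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ParameterError("mask must be a 2-D boolean array")
        if self.scale is not None and not self.scale > 0:
            raise ParameterError("scale must be strictly positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ComponentLabeling:
    """8-connected component labels (0 = background) and their sizes."""

    labels: np.ndarray
    sizes: np.ndarray  # sizes[k] = pixel count of component k+1

    @property
    def n_components(self) -> int:
        return len(self.sizes)


@dataclass
class SegmentationParams:
    """Parameters of the three thresholding algorithms.

    Defaults are the tool's standard configuration: global
    ``threshold_value=150``; adaptive ``mean_shift=-1.25`` over
    ``block_size=19`` windows; double-adaptive ``neighborhood_size=15``
    with ``bound_drop=5``; all with ``min_component_size=4000``.
    """

    algorithm: str = "global"
    threshold_value: float = 150.0
    block_size: int = 19
    mean_shift: float = -1.25
    neighborhood_size: int = 15
    bound_drop: float = 5.0
    min_component_size: int = 4000
    invert_polarity: bool = False

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown segmentation algorithm {self.algorithm!r}; "
                f"expected one of {ALGORITHMS}"
            )
        if self.algorithm == "global" and not 0 <= self.threshold_value <= 255:
            raise ParameterError(
                f"threshold_value must lie in [0, 255], got {self.threshold_value}"
            )
        if self.algorithm == "adaptive":
            if self.block_size < 3 or self.block_size % 2 == 0:
                raise ParameterError(
                    f"block_size must be an odd integer >= 3, got {self.block_size}"
                )
        if self.algorithm == "double_adaptive" and self.neighborhood_size < 3:
            raise ParameterError(
                f"neighborhood_size must be >= 3, got {self.neighborhood_size}"
            )
        if self.min_component_size < 0:
            raise ParameterError("min_component_size must be non-negative")

    def with_(self, **kwargs) -> "SegmentationParams":
        return replace(self, **kwargs)


def label_components(mask: BinaryMask | np.ndarray) -> ComponentLabeling:
    """Label 8-connected foreground components and measure their sizes."""
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    labels, n = ndi.label(pixels, structure=STRUCTURE_8)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ComponentLabeling(labels=labels, sizes=sizes)


def filter_small_components(mask: BinaryMask, min_size: int) -> BinaryMask:
    """Remove 8-connected components with strictly fewer than ``min_size`` pixels."""
    if min_size <= 1 or not mask.pixels.any():
        return BinaryMask(mask.pixels.copy(), scale=mask.scale)
    lab = label_components(mask)
    keep = np.flatnonzero(lab.sizes >= min_size) + 1
    out = np.isin(lab.labels, keep) if len(keep) else np.zeros_like(mask.pixels)
    return BinaryMask(out, scale=mask.scale)


def _truncated_window_mean(pixels: np.ndarray, size: int) -> np.ndarray:
    """Mean over the size x size window centred on each pixel, windows
    truncated (not padded) at the image border."""
    sums = ndi.uniform_filter(pixels, size, mode="constant", cval=0.0) * (size * size)
    counts = ndi.uniform_filter(
        np.ones_like(pixels), size, mode="constant", cval=0.0
    ) * (size * size)
    return sums / counts


def segment_global(img: GrayImage, p: SegmentationParams) -> BinaryMask:
    """Global thresholding: foreground iff intensity > threshold_value
    (< threshold_value when polarity is inverted)."""
    if p.algorithm != "global":
        raise ParameterError("segment_global requires algorithm='global'")
    p.validate()
    if p.invert_polarity:
        fg = img.pixels < p.threshold_value
    else:
        fg = img.pixels > p.threshold_value
    return filter_small_components(
        BinaryMask(fg, scale=img.scale), p.min_component_size
    )


def segment_adaptive(img: GrayImage, p: SegmentationParams) -> BinaryMask:
    """Adaptive (local mean) thresholding."""
    if p.algorithm != "adaptive":
        raise ParameterError("segment_adaptive requires algorithm='adaptive'")
    p.validate()
    pixels = 255.0 - img.pixels if p.invert_polarity else img.pixels
    mean = _truncated_window_mean(pixels, p.block_size)
    fg = pixels > mean + p.mean_shift
    return filter_small_components(
        BinaryMask(fg, scale=img.scale), p.min_component_size
    )


def segment_double_adaptive(img: GrayImage, p: SegmentationParams) -> BinaryMask:
    """Double-adaptive thresholding via growing centred squares.

    A pixel is foreground iff the mean over some centred square of side
    3, 5, ..., up to the largest odd size <= ``neighborhood_size`` falls
    to at most the pixel's own intensity minus ``bound_drop``.
    """
    if p.algorithm != "double_adaptive":
        raise ParameterError(
            "segment_double_adaptive requires algorithm='double_adaptive'"
        )
    p.validate()
    pixels = 255.0 - img.pixels if p.invert_polarity else img.pixels
    k_max = (p.neighborhood_size - 1) // 2
    min_mean = pixels.copy()  # m(0) = the pixel's own intensity
    for k in range(1, k_max + 1):
        np.minimum(min_mean, _truncated_window_mean(pixels, 2 * k + 1), out=min_mean)
    fg = min_mean <= pixels - p.bound_drop
    return filter_small_components(
        BinaryMask(fg, scale=img.scale), p.min_component_size
    )


_DISPATCH = {
    "global": segment_global,
    "adaptive": segment_adaptive,
    "double_adaptive": segment_double_adaptive,
}


def segment(img: GrayImage, p: SegmentationParams) -> BinaryMask:
    """Segment an image with the algorithm selected in ``p``."""
    if p.algorithm not in _DISPATCH:
        raise ConfigurationError(
            f"unknown segmentation algorithm {p.algorithm!r}; "
            f"expected one of {ALGORITHMS}"
        )
    return _DISPATCH[p.algorithm](img, p)
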