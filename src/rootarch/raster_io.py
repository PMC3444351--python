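"""Image import, preprocessing and scale calibration.

Images are held as 2-D float arrays of intensities normalized to the
[0, 255] range regardless of the source bit depth, so that threshold
parameters are comparable across 8-bit and 16-bit inputs.  Pixel
coordinates are 0-based and row-major with the origin at the top-left
corner; "depth" always means increasing row index.  Crop extents are
half-open.

Folders of images are organized into *stacks*: every image imported
from the same folder shares a stack identifier (the folder's path
relative to the import root), which is the addressing unit for
per-stack configuration directives.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

from .errors import ParameterError, PreconditionError

__all__ = [
    "GrayImage",
    "CropRect",
    "ImportResult",
    "IMAGE_EXTENSIONS",
    "load_image",
    "import_images",
    "preprocess",
    "set_scale",
    "scale_from_line",
    "write_png",
    "to_uint8",
]

#: Raster extensions recognized during folder import (case-insensitive).
IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")

# ITU-R 601 luma weights for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A 2-D grayscale raster with optional physical scale.

    Parameters
    ----------
    pixels : ndarray of float
        Intensities in [0, 255], shape ``(height, width)``.
    scale : float, optional
        Pixels per centimetre.  When absent, downstream traits are
        reported in pixel units.
    source_path : str
        Path the image was loaded from ("" for in-memory images).
    stack_id : str
        Identifier of the stack (folder) the image belongs to.
    image_id : str
        Short identifier used in reports; defaults to the file stem.
    """

    pixels: np.ndarray
    scale: float | None = None
    source_path: str = ""
    stack_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ParameterError("image must be a 2-D array with at least one pixel")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 255.0:
            raise ParameterError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")
        if self.scale is not None and not self.scale > 0:
            raise ParameterError(f"scale must be strictly positive, got {self.scale}")
        if not self.image_id and self.source_path:
            self.image_id = Path(self.source_path).stem

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CropRect:
    """Half-open crop window ``[row0, row0+n_rows) x [col0, col0+n_cols)``."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("crop extent must cover at least one pixel")
        if self.row0 < 0 or self.col0 < 0:
            raise ParameterError("crop origin must be non-negative")

    def check_inside(self, height: int, width: int) -> None:
        if self.row0 + self.n_rows > height or self.col0 + self.n_cols > width:
            raise PreconditionError(
                f"crop {self} exceeds image bounds ({height}x{width})"
            )


@dataclass
class ImportResult:
    """Outcome of a batch import: loaded images plus per-file errors."""

    images: list[GrayImage] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)

    def stacks(self) -> dict[str, list[GrayImage]]:
        out: dict[str, list[GrayImage]] = {}
        for img in self.images:
            out.setdefault(img.stack_id, []).append(img)
        return out


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Map any integer/float raster onto the [0, 255] float range."""
    arr = np.asarray(arr)
    if arr.ndim == 3:  # color: keep RGB, drop alpha, apply luma weighting
        arr = arr[..., :3].astype(np.float64) @ _LUMA
        scale_from = 255.0  # PIL decodes color images as 8-bit per channel
    elif arr.dtype == np.uint8:
        arr = arr.astype(np.float64)
        scale_from = 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64)
        scale_from = 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64)
        scale_from = max(float(arr.max()), 255.0)
    else:  # float input assumed already in display range
        arr = arr.astype(np.float64)
        scale_from = 255.0 if arr.max() <= 255.0 else float(arr.max())
    return np.clip(arr * (255.0 / scale_from), 0.0, 255.0)


def load_image(path: str | os.PathLike, stack_id: str = "") -> GrayImage:
    """Load one raster file as a :class:`GrayImage`.

    Color inputs are converted to grayscale with ITU-R 601 luma weights;
    intensities are normalized to [0, 255] whatever the source bit depth.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    return GrayImage(_normalize(arr), source_path=str(path), stack_id=stack_id)


def import_images(root_folder: str | os.PathLike, recursive: bool = False) -> ImportResult:
    """Import every recognized raster under ``root_folder``.

    Images are grouped into stacks by their containing folder (path
    relative to ``root_folder``; ``"."`` for the root itself) and ordered
    lexicographically by filename within each stack.  Unreadable files
    are recorded as per-file errors and do not abort the batch.
    """
    root = Path(root_folder)
    if not root.is_dir():
        raise PreconditionError(f"not a readable folder: {root}")
    folders = [root]
    if recursive:
        folders += sorted(p for p in root.rglob("*") if p.is_dir())
    result = ImportResult()
    for folder in folders:
        stack_id = os.path.normpath(os.path.relpath(folder, root))
        files = sorted(
            p for p in folder.iterdir()
            if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
        )
        for path in files:
            try:
                result.images.append(load_image(path, stack_id=stack_id))
            except Exception as exc:  # noqa: BLE001 - per-file isolation
                result.errors.append((str(path), f"{type(exc).__name__}: {exc}"))
    return result


def preprocess(
    img: GrayImage,
    crop: CropRect | None = None,
    rotation_deg: float | None = None,
) -> GrayImage:
    """Apply the standard preprocessing transformations: crop, then rotate.

    Rotation is counter-clockwise about the image centre with bilinear
    interpolation; the output canvas grows to contain the rotated extent
    and is filled with 0.  Multiples of 90 degrees are applied exactly.
    Scale metadata is carried through unchanged.
    """
    pixels = img.pixels
    if crop is not None:
        crop.check_inside(img.height, img.width)
        pixels = pixels[
            crop.row0 : crop.row0 + crop.n_rows, crop.col0 : crop.col0 + crop.n_cols
        ]
    if rotation_deg is not None and not math.isclose(rotation_deg % 360.0, 0.0):
        angle = rotation_deg % 360.0
        if math.isclose(angle % 90.0, 0.0):
            pixels = np.rot90(pixels, k=int(round(angle / 90.0)))
        else:
            pixels = ndi.rotate(
                pixels, angle, reshape=True, order=1, mode="constant", cval=0.0
            )
            pixels = np.clip(pixels, 0.0, 255.0)
    else:
        pixels = pixels.copy()
    return GrayImage(
        pixels,
        scale=img.scale,
        source_path=img.source_path,
        stack_id=img.stack_id,
        image_id=img.image_id,
    )


def set_scale(
    images: GrayImage | Sequence[GrayImage],
    pixels_per_cm: float,
    apply_to: str = "image",
    stack_id: str | None = None,
) -> list[GrayImage]:
    """Set the pixels/cm calibration on one image, one stack, or all images.

    ``apply_to`` is one of ``"image"`` (first argument is a single
    image), ``"stack"`` (all images whose ``stack_id`` matches) or
    ``"all"``.  Images are updated in place; the updated ones are
    returned.
    """
    if not pixels_per_cm > 0:
        raise ParameterError(f"pixels_per_cm must be positive, got {pixels_per_cm}")
    if apply_to == "image":
        if not isinstance(images, GrayImage):
            raise ParameterError("apply_to='image' expects a single GrayImage")
        images.scale = float(pixels_per_cm)
        return [images]
    if isinstance(images, GrayImage):
        raise ParameterError(f"apply_to={apply_to!r} expects a sequence of images")
    targets: Iterable[GrayImage]
    if apply_to == "stack":
        if stack_id is None:
            raise ParameterError("apply_to='stack' requires stack_id")
        targets = [im for im in images if im.stack_id == stack_id]
    elif apply_to == "all":
        targets = list(images)
    else:
        raise ParameterError(f"unknown apply_to scope: {apply_to!r}")
    updated = []
    for im in targets:
        im.scale = float(pixels_per_cm)
        updated.append(im)
    return updated


def scale_from_line(length_px: float, length_cm: float) -> float:
    """Calibration from a drawn reference line: pixels/cm = px / cm."""
    if not length_px > 0 or not length_cm > 0:
        raise ParameterError("line length must be positive in both units")
    return length_px / length_cm


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Round a [0, 255] float raster to uint8 for export."""
    return np.clip(np.rint(np.asarray(pixels)), 0, 255).astype(np.uint8)


def write_png(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a grayscale (or boolean) raster as an 8-bit PNG."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = to_uint8(arr)
    Image.fromarray(arr, mode="L").save(path, format="PNG")
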