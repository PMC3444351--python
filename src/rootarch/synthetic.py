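"""Synthetic root-image phantoms with exact ground truth.

Phantoms emulate gel-imaged root systems — bright, thin, branching
structures on a darker, possibly gradient-lit and noisy background —
while keeping the ground-truth mask exact: elements are drawn directly
in pixel space with no anti-aliasing, and blur/noise/speckle corruption
is applied only to the rendered grayscale image, never to the mask.
Where a closed form exists (bars, combs), the generator also returns
analytically known trait values.

Every phantom is a pure function of its spec and seed, so renders are
bit-reproducible.

Render presets (:func:`noise_presets`) reproduce the image regimes that
drive the choice of thresholding algorithm:

``clean``
    Uniform background; any algorithm with sensible parameters recovers
    the mask exactly.
``gradient``
    A strong vertical illumination gradient plus a sparse grid of
    bright single-pixel dots.  No single global threshold separates
    roots from background, while local-mean thresholding does: the dots
    pull every local window mean above the smooth background level, so
    background pixels fall below mean + mean_shift, and the dots
    themselves are erased by the small-component filter.
``speckled``
    Uniform background with small bright squares that the
    minimum-component-size filter must remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import PhantomSpecError
from .raster_io import GrayImage
from .segmentation import BinaryMask

__all__ = [
    "VerticalBar",
    "SlantedSegment",
    "Comb",
    "Annulus",
    "Disk",
    "RenderModel",
    "PhantomSpec",
    "make_phantom",
    "noise_presets",
    "fixture_catalog",
    "gradient_phantom",
    "dense_crown_phantom",
    "speckled_phantom",
    "make_fixtures",
]


# -- drawable elements --------------------------------------------------


@dataclass(frozen=True)
class VerticalBar:
    """Solid axis-aligned bar: rows [top, top+length), cols [left, left+width)."""

    top: int
    left: int
    width: int
    length: int

    def draw(self, mask: np.ndarray) -> None:
        mask[self.top : self.top + self.length, self.left : self.left + self.width] = True

    def bounds(self):
        return self.top, self.left, self.top + self.length, self.left + self.width


@dataclass(frozen=True)
class SlantedSegment:
    """One-pixel-wide digital line segment between two pixel centres."""

    r0: int
    c0: int
    r1: int
    c1: int

    def draw(self, mask: np.ndarray) -> None:
        from skimage.draw import line

        rr, cc = line(self.r0, self.c0, self.r1, self.c1)
        mask[rr, cc] = True

    def bounds(self):
        return (min(self.r0, self.r1), min(self.c0, self.c1),
                max(self.r0, self.r1) + 1, max(self.c0, self.c1) + 1)


@dataclass(frozen=True)
class Comb:
    """A horizontal spine with evenly spaced vertical teeth hanging below."""

    top: int
    left: int
    n_teeth: int
    tooth_len: int
    tooth_width: int = 3
    spacing: int = 12  # left edge to left edge
    spine_height: int = 3

    def draw(self, mask: np.ndarray) -> None:
        _, _, rmax, cmax = self.bounds()
        mask[self.top : self.top + self.spine_height, self.left : cmax] = True
        for i in range(self.n_teeth):
            c = self.left + i * self.spacing
            mask[
                self.top + self.spine_height : rmax, c : c + self.tooth_width
            ] = True

    def bounds(self):
        cmax = self.left + (self.n_teeth - 1) * self.spacing + self.tooth_width
        return (self.top, self.left,
                self.top + self.spine_height + self.tooth_len, cmax)


@dataclass(frozen=True)
class Annulus:
    """Ring: pixels with r_inner^2 < distance^2 <= r_outer^2 from the centre."""

    cr: int
    cc: int
    r_outer: float
    r_inner: float

    def draw(self, mask: np.ndarray) -> None:
        yy, xx = np.ogrid[: mask.shape[0], : mask.shape[1]]
        d2 = (yy - self.cr) ** 2 + (xx - self.cc) ** 2
        mask |= (d2 <= self.r_outer**2) & (d2 > self.r_inner**2)

    def bounds(self):
        r = int(math.ceil(self.r_outer))
        return self.cr - r, self.cc - r, self.cr + r + 1, self.cc + r + 1


@dataclass(frozen=True)
class Disk:
    """Solid disk: pixels within ``radius`` of the centre."""

    cr: int
    cc: int
    radius: float

    def draw(self, mask: np.ndarray) -> None:
        yy, xx = np.ogrid[: mask.shape[0], : mask.shape[1]]
        mask |= (yy - self.cr) ** 2 + (xx - self.cc) ** 2 <= self.radius**2

    def bounds(self):
        r = int(math.ceil(self.radius))
        return self.cr - r, self.cc - r, self.cr + r + 1, self.cc + r + 1


# -- rendering ----------------------------------------------------------


@dataclass(frozen=True)
class RenderModel:
    """How the ground-truth mask is turned into a grayscale image.

    ``bg_gradient`` (top, bottom intensities) overrides ``bg_level``.
    Foreground is drawn at ``fg_level`` unless ``fg_offset`` is set, in
    which case it sits at background + offset (clipped to 255).
    ``dot_grid`` = (spacing, amplitude) scatters isolated bright
    single-pixel dots on a regular grid over the background, at least
    two pixels away from any root pixel.  Speckles are ``speckle_size``
    x ``speckle_size`` bright squares at seeded random background
    positions, disjoint from the root and from each other.
    """

    bg_level: float = 20.0
    bg_gradient: tuple[float, float] | None = None
    fg_level: float = 220.0
    fg_offset: float | None = None
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    speckle_count: int = 0
    speckle_size: int = 3
    dot_grid: tuple[int, float] | None = None
    invert: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    """A phantom: canvas, drawable elements, render model and seed."""

    shape: tuple[int, int]
    elements: tuple
    render: RenderModel = RenderModel()
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))


def _ground_truth_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    mask = np.zeros((h, w), dtype=bool)
    for el in spec.elements:
        r0, c0, r1, c1 = el.bounds()
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise PhantomSpecError(f"element {el} lies outside the {h}x{w} canvas")
        el.draw(mask)
    return mask


def _known_traits(spec: PhantomSpec, mask: np.ndarray) -> dict[str, float]:
    """Closed-form trait values, where the geometry admits them."""
    known: dict[str, float] = {"NwA": float(mask.sum())}
    if len(spec.elements) == 1 and isinstance(spec.elements[0], VerticalBar):
        bar = spec.elements[0]
        w, length = bar.width, bar.length
        known.update(
            Ndepth=float(length), Nwidth=float(w), WDRatio=w / length,
            MedR=1.0, MaxR=1.0, Bush=1.0, Solidity=1.0,
            Perim=float(w * length - max(0, (w - 2) * (length - 2))),
            Ldist=(length - math.ceil(length / 3)) / length,
        )
        if w % 2 == 1:  # odd widths have an exactly centred axis
            known.update(
                Width=float(w),
                Nvol=math.pi * (w / 2.0) ** 2 * length,
                Nsurf=math.pi * w * length,
            )
    if len(spec.elements) == 1 and isinstance(spec.elements[0], Comb):
        comb = spec.elements[0]
        counts = [1] * comb.spine_height + [comb.n_teeth] * comb.tooth_len
        known.update(MedR=float(comb.n_teeth), MaxR=float(comb.n_teeth),
                     Ndepth=float(len(counts)))
    return known


def _place_speckles(mask: np.ndarray, render: RenderModel,
                    rng: np.random.Generator) -> np.ndarray:
    """Seeded speckle squares, 8-disjoint from the root and each other."""
    h, w = mask.shape
    s = render.speckle_size
    occupied = ndi.binary_dilation(mask, np.ones((2 * s + 3, 2 * s + 3)))
    speckles = np.zeros_like(mask)
    placed = 0
    attempts = 0
    while placed < render.speckle_count and attempts < 10000:
        attempts += 1
        r = int(rng.integers(0, h - s))
        c = int(rng.integers(0, w - s))
        if occupied[r : r + s, c : c + s].any():
            continue
        speckles[r : r + s, c : c + s] = True
        occupied[max(0, r - s - 1) : r + 2 * s + 1,
                 max(0, c - s - 1) : c + 2 * s + 1] = True
        placed += 1
    if placed < render.speckle_count:
        raise PhantomSpecError("could not place all speckles disjointly")
    return speckles


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, BinaryMask, dict[str, float]]:
    """Render a phantom: grayscale image, exact ground-truth mask, known traits.

    With no blur and no noise, thresholding the rendered image at the
    midpoint between background and foreground levels recovers the
    ground-truth mask exactly.
    """
    mask = _ground_truth_mask(spec)
    known = _known_traits(spec, mask)
    h, w = spec.shape
    render = spec.render
    rng = np.random.default_rng(spec.seed)

    if render.bg_gradient is not None:
        top, bottom = render.bg_gradient
        img = np.repeat(np.linspace(top, bottom, h)[:, None], w, axis=1)
    else:
        img = np.full((h, w), float(render.bg_level))

    if render.dot_grid is not None:
        spacing, amplitude = render.dot_grid
        dots = np.zeros((h, w), dtype=bool)
        dots[1::spacing, 1::spacing] = True
        dots &= ~ndi.binary_dilation(mask, np.ones((5, 5)))
        img[dots] += amplitude

    if render.fg_offset is not None:
        img[mask] += render.fg_offset
    else:
        img[mask] = render.fg_level

    if render.speckle_count > 0:
        speckles = _place_speckles(mask, render, rng)
        if render.fg_offset is not None:
            img[speckles] += render.fg_offset
        else:
            img[speckles] = render.fg_level

    if render.blur_sigma > 0:
        img = ndi.gaussian_filter(img, render.blur_sigma)
    if render.noise_sigma > 0:
        img = img + rng.normal(0.0, render.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    if render.invert:
        img = 255.0 - img
    gray = GrayImage(img, image_id=spec.name or "phantom", stack_id="synthetic")
    return gray, BinaryMask(mask.copy()), known


def noise_presets() -> dict[str, RenderModel]:
    """Named render models covering the main imaging regimes."""
    return {
        "clean": RenderModel(bg_level=20.0, fg_level=220.0),
        "gradient": RenderModel(
            bg_gradient=(30.0, 195.0), fg_offset=60.0, dot_grid=(3, 45.0)
        ),
        "speckled": RenderModel(
            bg_level=20.0, fg_level=220.0, speckle_count=30, speckle_size=3
        ),
    }


# -- the standard fixture suite ----------------------------------------


def fixture_catalog(seed: int = 0) -> list[PhantomSpec]:
    """The standard suite of clean phantoms with exact ground truth.

    Bars of drawn widths 1, 3 and 5 px at two lengths each, a slanted
    segment, combs, an annulus, a disk, and a two-bar pair: enough
    variety to exercise every trait with known answers.
    """
    clean = noise_presets()["clean"]

    def spec(name, shape, elements, s=0):
        return PhantomSpec(shape=shape, elements=tuple(elements), render=clean,
                           seed=seed + s, name=name)

    return [
        spec("bar_w1_l60", (80, 40), [VerticalBar(10, 20, 1, 60)]),
        spec("bar_w1_l120", (140, 40), [VerticalBar(10, 20, 1, 120)]),
        spec("bar_w3_l60", (80, 40), [VerticalBar(10, 18, 3, 60)]),
        spec("bar_w3_l120", (140, 40), [VerticalBar(10, 18, 3, 120)]),
        spec("bar_w5_l60", (80, 40), [VerticalBar(10, 17, 5, 60)]),
        spec("bar_w5_l120", (140, 40), [VerticalBar(10, 17, 5, 120)]),
        spec("slant_diag", (80, 80), [SlantedSegment(10, 10, 69, 60)]),
        spec("comb_3teeth", (80, 60), [Comb(10, 10, 3, 50, spacing=15)]),
        spec("comb_5teeth", (100, 80), [Comb(10, 8, 5, 60, spacing=13)]),
        spec("annulus", (90, 90), [Annulus(44, 44, 30.0, 18.0)]),
        spec("disk", (70, 70), [Disk(34, 34, 22.0)]),
        spec("two_bars", (120, 60), [VerticalBar(10, 15, 3, 100),
                                     VerticalBar(10, 40, 5, 100)]),
        spec("bar_and_disk", (120, 100), [VerticalBar(10, 20, 3, 100),
                                          Disk(60, 70, 15.0)]),
    ]


def gradient_phantom(seed: int = 0) -> PhantomSpec:
    """Reference phantom for the illumination-gradient regime.

    Eight thick bars joined by a crown spine (about 11% of the canvas,
    one connected network) under a strong vertical background gradient:
    built so no single global threshold can reach a low error while
    local-mean thresholding with default parameters can.
    """
    spine = VerticalBar(25, 16, 226, 4)  # horizontal slab joining the bars
    bars = tuple(VerticalBar(25, 16 + 30 * i, 4, 205) for i in range(8))
    bars = (spine,) + bars
    return PhantomSpec(shape=(256, 256), elements=bars,
                       render=noise_presets()["gradient"], seed=seed,
                       name="gradient_bars")


def dense_crown_phantom(nh: int = 15, seed: int = 0) -> PhantomSpec:
    """A bar much wider than the double-adaptive neighborhood.

    Interior pixels deeper than the neighborhood half-size from the bar
    edge never see the mean drop, so double-adaptive thresholding leaves
    the dense interior unsegmented.
    """
    width = 2 * nh  # comfortably wider than the growing-square reach
    return PhantomSpec(shape=(160, 120), elements=(VerticalBar(20, 45, width, 120),),
                       render=noise_presets()["clean"], seed=seed,
                       name="dense_crown")


def speckled_phantom(seed: int = 0) -> PhantomSpec:
    """A root bar plus bright speckles for the component-size filter."""
    return PhantomSpec(shape=(160, 160), elements=(VerticalBar(15, 78, 5, 130),),
                       render=noise_presets()["speckled"], seed=seed,
                       name="speckled_bar")


def make_fixtures(out_folder, seed: int = 0) -> list[str]:
    """Write the standard fixture suite to disk (images + GT masks + truths)."""
    import json
    from pathlib import Path

    from .raster_io import write_png

    out = Path(out_folder)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    specs = fixture_catalog(seed=seed) + [
        gradient_phantom(seed=seed),
        dense_crown_phantom(seed=seed),
        speckled_phantom(seed=seed),
    ]
    for spec in specs:
        img, gt, known = make_phantom(spec)
        img_path = out / f"{spec.name}.png"
        write_png(img_path, img.pixels)
        write_png(out / f"{spec.name}.gt.png", gt.pixels)
        (out / f"{spec.name}.traits.json").write_text(
            json.dumps(known, indent=2, sort_keys=True) + "\n"
        )
        written.append(str(img_path))
    return written
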