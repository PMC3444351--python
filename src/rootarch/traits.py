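"""The 19 root-system-architecture traits.

Traits are computed from the segmented mask (the *network*: the set of
all foreground pixels), from a vertical line sweep of per-row root
crossing counts, or from the medial-axis skeleton with its local radius
estimates.  All geometry is measured in pixels and converted to
physical units afterwards when a pixels/cm scale is attached:

==========  ===========  =======================================================
symbol      units        definition
==========  ===========  =======================================================
NwA         cm^2         number of network pixels (network area)
ConvA       cm^2         pixel area of the convex hull of the network
Solidity    ratio        NwA / ConvA
Ndepth      cm           vertical extent, topmost to bottommost network row
Nwidth      cm           maximum within-row horizontal extent
WDRatio     ratio        Nwidth / Ndepth
Perim       cm           network pixels with a background 8-neighbour
Ldist       ratio        fraction of network pixels in the lower 2/3 of the depth
MajA, MinA  cm           full axes of the moments-equivalent ellipse
AspR        ratio        MinA / MajA
MedR        count        median per-row root-crossing count (integer)
MaxR        count        84th-percentile per-row crossing count (nearest rank)
Bush        ratio        MaxR / MedR (bushiness)
Nlen        cm           number of skeleton pixels (network length)
Width       cm           mean local root diameter over skeleton pixels
Nvol        cm^3         sum over skeleton pixels of pi (w/2)^2 (tubular model)
Nsurf       cm^2         sum over skeleton pixels of pi w (tubular model)
SRL         cm/cm^3      Nlen / Nvol (specific root length, volume-based)
==========  ===========  =======================================================

Counts and ratios are dimensionless and unaffected by scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    EmptyNetworkError,
    UndefinedBushinessError,
)
from .segmentation import BinaryMask
from .skeleton import Skeleton, local_width

__all__ = [
    "TraitInfo",
    "TRAITS",
    "TRAIT_NAMES",
    "TraitRecord",
    "unit_label",
    "extent_traits",
    "convex_traits",
    "fit_ellipse",
    "sweep_root_counts",
    "count_traits",
    "skeleton_traits",
    "apply_scale",
    "compute_traits",
]


@dataclass(frozen=True)
class TraitInfo:
    """Catalog entry: name, physical dimension, substrate and definition."""

    name: str
    dimension: str  # length | area | volume | per_volume | count | ratio
    requires: str  # mask | row_counts | skeleton
    description: str


TRAITS: dict[str, TraitInfo] = {
    t.name: t
    for t in [
        TraitInfo("Bush", "ratio", "row_counts",
                  "Bushiness: ratio of the maximum to the median number of roots."),
        TraitInfo("ConvA", "area", "mask",
                  "Convex area: area of the convex hull that encompasses the network."),
        TraitInfo("Ndepth", "length", "mask",
                  "Network depth: vertical extent from the uppermost to the lowermost network pixel."),
        TraitInfo("Ldist", "ratio", "mask",
                  "Network length distribution: fraction of network pixels in the lower 2/3 of the network depth."),
        TraitInfo("MajA", "length", "mask",
                  "Major axis length of the best-fitting (moments-equivalent) ellipse."),
        TraitInfo("Nwidth", "length", "mask",
                  "Network width: maximum horizontal extent over single rows."),
        TraitInfo("MaxR", "count", "row_counts",
                  "Maximum number of roots: 84th-percentile of the sorted per-row crossing counts."),
        TraitInfo("Width", "length", "skeleton",
                  "Average root width (diameter): mean local width over all medial-axis pixels."),
        TraitInfo("MedR", "count", "row_counts",
                  "Median number of roots crossing a horizontal line, over the vertical extent of the network."),
        TraitInfo("MinA", "length", "mask",
                  "Minor axis length of the best-fitting (moments-equivalent) ellipse."),
        TraitInfo("NwA", "area", "mask",
                  "Network area: the number of network pixels in the image."),
        TraitInfo("Perim", "length", "mask",
                  "Perimeter: network pixels connected to a background pixel (8-nearest neighbours)."),
        TraitInfo("AspR", "ratio", "mask",
                  "Aspect ratio: minor over major axis of the best-fitting ellipse."),
        TraitInfo("Solidity", "ratio", "mask",
                  "Network solidity: network area divided by convex area."),
        TraitInfo("SRL", "per_volume", "skeleton",
                  "Specific root length: total network length divided by network volume."),
        TraitInfo("Nsurf", "area", "skeleton",
                  "Network surface area: sum of local tubular surface over skeleton pixels."),
        TraitInfo("Nlen", "length", "skeleton",
                  "Network length: total number of pixels in the network skeleton."),
        TraitInfo("Nvol", "volume", "skeleton",
                  "Network volume: sum of local tubular cross sections over skeleton pixels."),
        TraitInfo("WDRatio", "ratio", "mask",
                  "Network width-to-depth ratio."),
    ]
}

TRAIT_NAMES: tuple[str, ...] = tuple(TRAITS)

_SCALE_POWER = {"length": 1, "area": 2, "volume": 3, "per_volume": -2,
                "count": 0, "ratio": 0}

_UNIT = {
    ("length", "cm"): "cm", ("length", "px"): "px",
    ("area", "cm"): "cm^2", ("area", "px"): "px^2",
    ("volume", "cm"): "cm^3", ("volume", "px"): "px^3",
    ("per_volume", "cm"): "cm/cm^3", ("per_volume", "px"): "px/px^3",
    ("count", "cm"): "n", ("count", "px"): "n",
    ("ratio", "cm"): "ratio", ("ratio", "px"): "ratio",
}


def unit_label(trait: str, units: str, dimension: str | None = None) -> str:
    """Unit string for a trait under the given units flag ('cm' or 'px')."""
    dim = dimension or (TRAITS[trait].dimension if trait in TRAITS else "ratio")
    return _UNIT[(dim, units)]


@dataclass
class TraitRecord:
    """Named trait values for one image, with a units flag."""

    image_id: str = ""
    stack_id: str = ""
    units: str = "px"  # 'px' or 'cm'
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _foreground(mask: BinaryMask, image_id: str = "") -> np.ndarray:
    if not mask.pixels.any():
        raise EmptyNetworkError(image_id=image_id)
    return mask.pixels


def extent_traits(mask: BinaryMask) -> dict[str, float]:
    """Pixel-count and extent traits: Ndepth, Nwidth, WDRatio, NwA, Perim, Ldist."""
    fg = _foreground(mask)
    rows = np.flatnonzero(fg.any(axis=1))
    top, bottom = int(rows[0]), int(rows[-1])
    ndepth = bottom - top + 1
    # widest within-row extent
    nwidth = 0
    cols = np.arange(fg.shape[1])
    for r in rows:
        c = cols[fg[r]]
        nwidth = max(nwidth, int(c[-1] - c[0] + 1))
    nwa = int(fg.sum())
    # perimeter: foreground pixels with a background pixel among their
    # 8 neighbours; the image border counts as background
    interior = ndi.binary_erosion(fg, structure=np.ones((3, 3)), border_value=0)
    perim = int((fg & ~interior).sum())
    # lower 2/3 of the network: rows at or below top + ceil(Ndepth / 3)
    boundary = top + math.ceil(ndepth / 3)
    lower = int(fg[boundary:].sum())
    return {
        "Ndepth": float(ndepth),
        "Nwidth": float(nwidth),
        "WDRatio": nwidth / ndepth,
        "NwA": float(nwa),
        "Perim": float(perim),
        "Ldist": lower / nwa,
    }


def _hull_pixel_count(points: np.ndarray) -> int:
    """Pixels whose centres lie inside or on the convex hull of ``points``.

    Counting whole pixel centres (rather than polygon area) keeps
    NwA <= ConvA by construction, so Solidity <= 1 always holds.
    """
    points = points - points.min(axis=0)  # bbox frame: translation invariant
    try:
        hull = ConvexHull(points.astype(np.float64))
    except QhullError:
        # all points collinear: lattice points on the extremal segment
        d = points.max(axis=0) - points.min(axis=0)
        return int(math.gcd(int(d[0]), int(d[1]))) + 1
    (r0, c0), (r1, c1) = points.min(axis=0), points.max(axis=0)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = (grid @ a.T + b <= 1e-9).all(axis=1)
    return int(inside.sum())


def convex_traits(mask: BinaryMask) -> dict[str, float]:
    """Convex hull traits: ConvA (hull pixel count) and Solidity = NwA/ConvA."""
    fg = _foreground(mask)
    points = np.argwhere(fg)
    conva = _hull_pixel_count(points)
    return {"ConvA": float(conva), "Solidity": len(points) / conva}


def fit_ellipse(mask: BinaryMask) -> dict[str, float]:
    """Axes of the ellipse with the same second central moments as the network.

    Axis lengths are ``4 sqrt(lambda)`` for the eigenvalues of the 2x2
    central covariance of the foreground pixel coordinates.  Collinear
    networks give MinA = 0 and AspR = 0 (with a warning); fewer than two
    distinct pixels are a degenerate-geometry error.
    """
    fg = _foreground(mask)
    pts = np.argwhere(fg).astype(np.float64)
    if len(pts) < 2 or (pts == pts[0]).all():
        raise DegenerateGeometryError(
            "best-fit ellipse requires >= 2 distinct foreground pixels"
        )
    pts -= pts.min(axis=0)  # bounding-box frame: exact translation invariance
    cov = np.cov(pts.T, bias=True)
    eigvals = np.clip(np.sort(np.linalg.eigvalsh(cov)), 0.0, None)
    maja = 4.0 * math.sqrt(eigvals[1])
    mina = 4.0 * math.sqrt(eigvals[0])
    if mina == 0.0:
        warnings.warn("collinear network: minor ellipse axis degenerates to 0",
                      stacklevel=2)
        return {"MajA": maja, "MinA": 0.0, "AspR": 0.0}
    return {"MajA": maja, "MinA": mina, "AspR": mina / maja}


def sweep_root_counts(mask: BinaryMask) -> np.ndarray:
    """Vertical line sweep: per-row count of root crossings.

    For every row of the network's vertical extent (topmost to
    bottommost inclusive), counts the maximal horizontal runs of
    foreground pixels; rows with no foreground inside the extent are
    recorded as 0.
    """
    fg = _foreground(mask)
    rows = np.flatnonzero(fg.any(axis=1))
    band = fg[rows[0] : rows[-1] + 1]
    padded = np.pad(band, ((0, 0), (1, 0)))  # run starts = False -> True edges
    starts = band & ~padded[:, :-1]
    return starts.sum(axis=1).astype(np.int64)


def count_traits(rc: np.ndarray) -> dict[str, float]:
    """MedR, MaxR and bushiness from the per-row crossing counts.

    MedR is the median (mean of the middle two for even length) rounded
    half-up to an integer, as root counts are integers.  MaxR is the
    84th-percentile by nearest rank (index ``ceil(0.84 n)`` in the
    ascending sort), the conventional one-standard-deviation surrogate
    for the maximum.  Bush = MaxR / MedR.
    """
    counts = np.sort(np.asarray(rc, dtype=np.int64))
    n = len(counts)
    if n == 0:
        raise EmptyNetworkError("no rows in the sweep")
    mid = n // 2
    med = float(counts[mid]) if n % 2 else (counts[mid - 1] + counts[mid]) / 2.0
    medr = math.floor(med + 0.5)  # round half-up
    maxr = int(counts[math.ceil(0.84 * n) - 1])
    if medr == 0:
        raise UndefinedBushinessError()
    return {"MedR": float(medr), "MaxR": float(maxr), "Bush": maxr / medr}


def skeleton_traits(sk: Skeleton) -> dict[str, float]:
    """Skeleton traits under the local tubular model.

    Each skeleton pixel contributes one pixel of length, a cross section
    of ``pi (w/2)^2`` to the volume, and ``pi w`` to the surface, where
    ``w`` is its local width (diameter).
    """
    if len(sk) == 0:
        raise EmptyNetworkError("skeleton is empty")
    w = local_width(sk)
    nlen = float(len(sk))
    nvol = float(np.sum(math.pi * (w / 2.0) ** 2))
    nsurf = float(np.sum(math.pi * w))
    return {
        "Nlen": nlen,
        "Width": float(w.mean()),
        "Nvol": nvol,
        "Nsurf": nsurf,
        "SRL": nlen / nvol,
    }


def apply_scale(rec: TraitRecord, pixels_per_cm: float,
                dimensions: dict[str, str] | None = None) -> TraitRecord:
    """Convert a pixel-unit record to centimetre units.

    Lengths divide by s, areas by s^2, volumes by s^3; SRL multiplies by
    s^2 (px/px^3 -> cm/cm^3); counts and ratios are unchanged.  Traits
    outside the built-in catalog default to ratio (unchanged) unless a
    dimension is supplied via ``dimensions``.
    """
    if not pixels_per_cm > 0:
        raise ConfigurationError("pixels_per_cm must be positive")
    if rec.units == "cm":
        return replace(rec, values=dict(rec.values))
    values = {}
    for name, v in rec.values.items():
        if name in TRAITS:
            dim = TRAITS[name].dimension
        elif dimensions and name in dimensions:
            dim = dimensions[name]
        else:
            dim = "ratio"
        values[name] = v / pixels_per_cm ** _SCALE_POWER[dim]
    return replace(rec, units="cm", values=values)


def compute_traits(
    mask: BinaryMask,
    selected: set[str] | None = None,
    image_id: str = "",
    stack_id: str = "",
    registry=None,
) -> TraitRecord:
    """Compute the selected traits for one mask.

    Stages are resolved through the plugin registry, so only the
    transformations a selection actually needs run (skeletonization is
    skipped when no skeleton trait is selected).  The record is scaled
    to cm units iff the mask carries a pixels/cm calibration.
    """
    from .plugins import get_default_registry  # late import: avoids cycle

    reg = registry if registry is not None else get_default_registry()
    known = reg.trait_names()
    names = list(selected) if selected is not None else list(TRAIT_NAMES)
    unknown = sorted(set(names) - set(known))
    if unknown:
        raise ConfigurationError(f"unknown trait name(s): {', '.join(unknown)}")
    if not mask.pixels.any():
        raise EmptyNetworkError(image_id=image_id)
    plan = reg.resolve({f"trait:{t}" for t in names}, available={"segmented_mask"})
    try:
        context = reg.run_plan(plan, {"segmented_mask": mask})
    except (UndefinedBushinessError, EmptyNetworkError) as exc:
        exc.image_id = image_id
        raise type(exc)(str(exc.args[0]) if exc.args else "", image_id=image_id) from exc
    values = {t: context[f"trait:{t}"] for t in names}
    # keep catalog order for reproducible output, extras after
    ordered = {t: values[t] for t in TRAIT_NAMES if t in values}
    ordered.update({t: v for t, v in values.items() if t not in ordered})
    rec = TraitRecord(image_id=image_id, stack_id=stack_id, units="px", values=ordered)
    if mask.scale is not None:
        rec = apply_scale(rec, mask.scale, dimensions=reg.trait_dimensions())
    return rec
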