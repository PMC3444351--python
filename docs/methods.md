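# Methods

This note documents the models and numerical conventions behind
`rootarch`, the choices made where several conventions were defensible,
and what the synthetic test suite does and does not demonstrate.

## Image model and coordinates

Images are 2-D intensity rasters normalized to the [0, 255] float range
on load, whatever the source bit depth (8-bit PNG/JPEG, 16-bit TIFF),
so that threshold parameters mean the same thing across acquisition
setups. Color inputs are collapsed with ITU-R 601 luma weights
(0.299 R + 0.587 G + 0.114 B) — any fixed weighting would do; luma is
the convention. Pixel coordinates are 0-based, row-major, origin at the
top left; "depth" is increasing row index. Crop windows are half-open.
Preprocessing applies crop first, then rotation (counter-clockwise,
bilinear, canvas grown to hold the rotated extent, fill 0; exact
`np.rot90` for multiples of 90°). The crop-then-rotate order is a fixed
convention; the operations do not commute and the configuration records
exactly what was done.

An optional scale (pixels/cm) travels with each image. Traits are
always computed in pixel units and converted once at the end: lengths
÷ s, areas ÷ s², volumes ÷ s³, specific root length × s²; counts and
ratios are dimensionless. This makes scale handling exactly
equivariant: computing on a calibrated mask equals computing
uncalibrated and converting, bit for bit.

## Segmentation

Three thresholding rules, all with strict inequalities (a pixel exactly
at the threshold is background):

- **Global**: foreground iff `I > tv`. Default `tv = 150`.
- **Adaptive (local mean)**: foreground iff `I > m + ms` with `m` the
  mean over the `bs × bs` window centred on the pixel. Defaults
  `bs = 19`, `ms = −1.25`. Windows are *truncated* at the image border
  (the mean is over in-bounds pixels only) rather than mirrored or
  padded, so no intensities are invented. Note the default offset is
  negative: on a perfectly flat background every pixel passes the test;
  the algorithm relies on the component-size filter to discard the
  resulting background plateau, and on real (textured) backgrounds the
  local mean sits above most background pixels.
- **Double-adaptive (growing squares)**: foreground iff the mean over
  some centred square of side 3, 5, …, up to the largest odd size
  ≤ `nh` falls to at most `I − bd`, with the reference `m(0)` taken as
  the pixel's own intensity. Defaults `nh = 15`, `bd = 5`. Pixels
  deeper than `(nh−1)/2` inside a bright region never see the drop,
  which is why this rule omits dense root crowns while giving clean
  edges on isolated roots — a documented behaviour, not a bug.

Polarity: a single `invert_polarity` flag serves dark-on-light imagery.
Global reverses the comparison (`I < tv`); the adaptive rules operate
on the inverted intensities `255 − I`, which is algebraically identical
to segmenting the inverted image with the standard rule.

All algorithms finish by removing 8-connected foreground components
with strictly fewer than `cs` pixels (default 4000). The filter always
runs last, is idempotent and never adds pixels. 8-connectivity is used
for all component logic, matching the 8-neighbour perimeter definition.

## Skeleton and local radius

The mask is thinned with the Guo–Hall morphological thinning
(`skimage.morphology.thin`), which preserves topology: the skeleton has
the same 8-connected component count and the same hole count as the
mask. This variant was selected after verifying topology preservation
empirically on randomized masks; the per-pixel radius is the exact
Euclidean distance transform of the mask (not a chamfer approximation)
evaluated at skeleton pixels, so `r ≥ 1` everywhere and a `w`-pixel bar
has `r = (w+1)/2` on its axis. Local diameter is defined as
`w = 2r − 1`, the pixel-centre convention under which a drawn bar
reports exactly its drawn width. No spur pruning is performed; dense
crowns therefore contribute short side branches to the skeleton, which
slightly inflates length-type traits on blobby regions.

One known limitation: raster-order thinning is not pixelwise
equivariant under 90° rotation for arbitrary shapes (the axis of a
perfectly round blob is orientation-dependent). Bars, rings and other
unambiguous shapes thin identically in both orientations, and the two
routes always agree topologically; mask-derived traits are exactly
rotation-invariant regardless.

## Traits

Mask traits: `NwA` is the foreground pixel count. `Ndepth` and `Nwidth`
are the vertical extent and the maximum *within-row* horizontal extent
(a diagonal network can be narrower in every single row than its
bounding box). `Perim` counts foreground pixels with a background pixel
among their 8 neighbours, with the image border treated as background.
`Ldist` is the fraction of network pixels at or below row
`top + ⌈Ndepth/3⌉`, i.e. in the lower two thirds of the depth extent.
`ConvA` counts the pixels whose centres lie inside or on the convex
hull of the foreground pixel centres — counting whole pixels (rather
than taking the polygon area) guarantees `NwA ≤ ConvA` and hence
`Solidity = NwA/ConvA ≤ 1`. Collinear networks get the lattice-point
count of the hull segment. The best-fit ellipse is the ellipse with the
same second central moments as the pixel-centre set; axis lengths are
`4√λ` of the 2×2 covariance eigenvalues (biased, coordinates taken in
the bounding-box frame for exact translation invariance). A single
pixel is a degenerate-geometry error; collinear networks report
`MinA = AspR = 0` with a warning.

Counting traits: a vertical line sweep counts, for every row of the
vertical extent (empty rows inside the extent count 0), the maximal
horizontal runs of foreground pixels. `MedR` is the median of these
counts, reported as an integer (mean of the middle two for even length,
rounded half-up) because a root count is an integer. `MaxR` is the
84th-percentile by nearest rank — index `⌈0.84 n⌉` of the ascending
sort, no interpolation — the conventional one-standard-deviation
surrogate for a noise-robust maximum. `Bush = MaxR/MedR` is undefined
(an error carrying the image id) when `MedR = 0`.

Skeleton traits model the root locally as a tube of diameter `w` and
unit pixel length at every skeleton pixel: `Nlen = Σ 1` (a pixel count,
deliberately, with no √2 diagonal correction — a divergence from
geometric arc length that keeps the definition exact and simple),
`Nvol = Σ π(w/2)²`, `Nsurf = Σ πw`, `Width = mean(w)`, and
`SRL = Nlen/Nvol` (volume-based, despite the name's conventional
mass-based meaning elsewhere).

## Pipeline and reproducibility

A run is fully specified by an XML configuration: scoped preprocessing
directives and segmentation parameter sets (precedence strictly
image > stack > global; field-wise for preprocessing, whole-set for
segmentation), the trait selection, export toggles, output folder and
worker count. Serialization is canonical — floats via `repr`, fixed
element order — so save → load → save is byte-stable and the snapshot
stored in every run manifest reproduces the run exactly. CSV floats are
rendered with a fixed `%.10g` format (integers as integers) so repeated
runs are byte-identical. Worker parallelism uses a thread pool with
order-preserving mapping; per-image failures are recorded in the
manifest and never affect other images. Only the stages a trait
selection needs are executed (no skeletonization for mask-only
selections), resolved through the plugin dependency graph with
deterministic, name-ordered tie-breaking.

## Synthetic phantoms: what they show and what they don't

The generator draws root-like elements (bars, slanted segments, combs,
annuli, disks) directly in pixel space with no anti-aliasing, so the
ground-truth mask is exact and extent/count traits have exact expected
values; blur, noise, speckles and illumination gradients corrupt only
the rendered grayscale image. Renders are pure functions of
(spec, seed).

Three presets emulate the imaging regimes that drive algorithm choice.
*clean* (flat background 20, foreground 220) — every algorithm recovers
the mask exactly at sensible parameters. *gradient* — a strong vertical
illumination ramp (30 → 195) with foreground at background + 60 and a
sparse 3-px grid of isolated bright dots (+45): the dots pull every
19×19 window mean a few intensity levels above the smooth background,
so default adaptive thresholding classifies background correctly while
the dots themselves are erased by the component filter; no single
global threshold gets the reference phantom (a connected 8-bar crown,
~11% of the canvas) below 5% pixel error, which is the point. *speckled*
— isolated 3×3 bright squares exercising the component-size filter.

Passing on phantoms demonstrates correctness of the measurement chain
on known geometry, not segmentation quality on real roots: phantoms
have no partial-volume edges, no touching/crossing root ambiguity, no
soil debris, and their backgrounds are far tamer than real gel images.
Parameter defaults still need per-dataset validation, which is what the
configuration scoping and intermediate exports are for.

Problem sizes used by the shipped test suite and acceptance script —
13 clean phantoms (plus the regime phantoms) for ground-truth recovery,
50 random 64×64 images per thresholding oracle, 200 random masks for
the invariant suite, 100 for topology, and 100 bar-crown phantoms at
1000×1000 for the throughput check — were chosen as the smallest sizes
at which the properties are non-trivially exercised.
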