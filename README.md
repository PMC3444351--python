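# rootarch

High-throughput estimation of root-system-architecture (RSA) traits
from images of root networks.

Plant biologists image washed or gel-grown root systems by the
thousands — bright, thin, branching structures on a darker, often
unevenly lit background — and need architectural phenotypes (how deep,
how wide, how bushy, how much root) extracted reproducibly and without
per-image human intervention. `rootarch` is a batch tool and library
for exactly that: it segments the root network out of each grayscale
image, thins it to a medial-axis skeleton with a local radius estimate
at every skeleton pixel, and measures 19 standard RSA traits, driven
entirely by a saved XML configuration so that every number in the
output can be regenerated from the configuration and the raw images.

## The method

**Segmentation.** The network (the set of root pixels) is separated
from background by one of three thresholding rules, selected per image,
per stack (folder) or globally:

- *global*: pixel `I > tv`, a fixed critical intensity (default
  `tv = 150`);
- *adaptive*: `I > m + ms`, where `m` is the mean over the
  `bs × bs` window centred on the pixel (defaults `bs = 19`,
  `ms = −1.25`; windows truncated at the border);
- *double-adaptive*: the mean over squares grown around the pixel
  (sides 3, 5, …, up to `nh = 15`) must drop by at least `bd = 5` below
  the pixel's own intensity — a rule that finds bright structures
  thinner than `nh` and deliberately ignores broad bright regions.

All three end by discarding 8-connected components smaller than `cs`
pixels (default 4000), which removes speckle and sensor noise. A single
polarity flag handles dark-roots-on-light-background imagery.

**Skeleton.** The mask is thinned to a one-pixel-wide, topology
preserving medial axis; each skeleton pixel carries radius `r`, its
Euclidean distance to the nearest background pixel, and local diameter
`w = 2r − 1` (so a bar drawn `w` pixels wide reports width `w`).

**Traits.** From the mask: network area `NwA` (pixel count), convex
area `ConvA`, solidity `NwA/ConvA`, depth/width extents, perimeter,
the lower-2/3 length distribution `Ldist`, and the axes of the
moments-equivalent ellipse (`MajA`, `MinA`, `AspR`). From a horizontal
line sweep of per-row root crossings: the median count `MedR`, the
84th-percentile count `MaxR`, and bushiness `Bush = MaxR/MedR`. From
the skeleton, modelling the root locally as a tube: length
`Nlen = Σ 1`, mean width, volume `Nvol = Σ π(w/2)²`, surface
`Nsurf = Σ πw`, and specific root length `SRL = Nlen/Nvol`. With a
pixels/cm calibration, lengths, areas and volumes are reported in cm,
cm², cm³; otherwise in pixel units.

Every transformation — each segmenter, the skeletonizer, every trait —
is a plugin declaring the data types it consumes and produces; new
traits drop in as a manifest + Python file with no change to the core.

## Worked example

Measure a synthetic root (a 5 px wide, 60 px long bar rendered on a
dark background) with a 50 px/cm calibration:

```python
from rootarch import synthetic
from rootarch.pipeline import PipelineConfig, ScopedSegmentation, export_csv, run
from rootarch.segmentation import SegmentationParams

spec = synthetic.fixture_catalog(seed=0)[4]   # 5 px wide, 60 px long bar
img, gt, known = synthetic.make_phantom(spec)
img.scale = 50.0                              # 50 px/cm calibration
config = PipelineConfig(
    segmentation=[ScopedSegmentation(SegmentationParams(
        algorithm="global", threshold_value=120.0, min_component_size=0))],
    traits=["Ndepth", "Nwidth", "NwA", "Width", "Nlen", "Nvol",
            "MedR", "Bush", "Solidity"],
    output_folder="")
records, manifest = run(config, [img])
export_csv(records, "traits.csv", trait_names=config.traits)
```

`traits.csv` then contains:

```
image,stack,units,Ndepth (cm),Nwidth (cm),NwA (cm^2),Width (cm),Nlen (cm),Nvol (cm^3),MedR (n),Bush (ratio),Solidity (ratio)
bar_w5_l60,synthetic,cm,1.2,0.1,0.12,0.1,1.12,0.00879645943,1,1,1
```

Reading it off: the bar is 60 px deep and 5 px wide, i.e. 1.2 cm ×
0.1 cm at 50 px/cm; its area is 300 px² = 0.12 cm²; the mean root
diameter recovered from the skeleton radii is exactly the drawn 0.1 cm;
one root crosses every horizontal line (`MedR = Bush = 1`) and the
shape is convex (`Solidity = 1`).

The same run from a shell, against a folder of images:

```
rootarch run --config project.xml --images scans/ --out results/ --workers 4
rootarch validate-config project.xml
rootarch list-traits
rootarch make-fixtures --out fixtures/ --seed 0
```

`results/` receives `traits.csv`, a `manifest.json` with per-image
status and artifact paths, the exact configuration snapshot
`project.xml`, and (if enabled) per-stage PNG intermediates. Exit
status is 0 only when every image succeeded, 1 on partial failures,
2 on configuration errors.

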