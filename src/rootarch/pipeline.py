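"""Batch driver, XML configuration and CSV/manifest output.

A :class:`PipelineConfig` fully specifies a run: preprocessing
directives (crop / rotation / scale), segmentation parameters, the
selected traits, intermediate-export toggles and the output folder.
Directives and segmentation parameters are *scoped*: ``global``,
``stack:<id>`` or ``image:<id>``, with strict image > stack > global
precedence, resolved field-wise for preprocessing and whole-parameter-set
for segmentation.

Configurations serialize to XML and round-trip losslessly
(save -> load -> save is byte-stable), and every run writes a manifest
recording per-image status, artifact paths and the exact configuration
snapshot, so any output can be reproduced from the manifest alone.
Batch output is deterministic: results are emitted in input order
whatever the worker count, and failures on one image never affect
another.
"""

from __future__ import annotations

import csv
import io
import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from lxml import etree

from . import __version__
from .errors import ConfigurationError, RootArchError
from .raster_io import CropRect, GrayImage, write_png
from .segmentation import ALGORITHMS, SegmentationParams, segment
from .skeleton import medial_axis, overlay
from .traits import TRAIT_NAMES, TRAITS, TraitRecord, compute_traits, unit_label

__all__ = [
    "PreprocessDirective",
    "ScopedSegmentation",
    "PipelineConfig",
    "RunManifest",
    "ImageResult",
    "run",
    "export_csv",
    "save_config",
    "load_config",
    "write_config",
]

_SCOPES = ("global", "stack", "image")


def _check_scope(scope: str) -> None:
    kind = scope.split(":", 1)[0]
    if kind not in _SCOPES or (kind != "global" and ":" not in scope):
        raise ConfigurationError(
            f"invalid scope {scope!r}; use 'global', 'stack:<id>' or 'image:<id>'"
        )


def _scope_rank(scope: str, image: GrayImage) -> int | None:
    """0 = global, 1 = matching stack, 2 = matching image, None = no match."""
    if scope == "global":
        return 0
    kind, _, target = scope.partition(":")
    if kind == "stack" and target == image.stack_id:
        return 1
    if kind == "image" and target == image.image_id:
        return 2
    return None


@dataclass(frozen=True)
class PreprocessDirective:
    """Scoped crop / rotation / scale directive."""

    scope: str = "global"
    crop: CropRect | None = None
    rotation_deg: float | None = None
    pixels_per_cm: float | None = None


@dataclass(frozen=True)
class ScopedSegmentation:
    """Segmentation parameter set attached to a scope."""

    params: SegmentationParams
    scope: str = "global"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a batch run."""

    preprocessing: list[PreprocessDirective] = field(default_factory=list)
    segmentation: list[ScopedSegmentation] = field(
        default_factory=lambda: [ScopedSegmentation(SegmentationParams())]
    )
    traits: list[str] = field(default_factory=lambda: list(TRAIT_NAMES))
    export_preprocessed: bool = False
    export_mask: bool = False
    export_skeleton: bool = False
    output_folder: str = "rootarch_out"
    workers: int = 1

    def validate(self, registry=None) -> None:
        if self.workers < 1:
            raise ConfigurationError("workers must be a positive integer")
        known = set(TRAIT_NAMES)
        if registry is not None:
            known |= set(registry.trait_names())
        unknown = sorted(set(self.traits) - known)
        if unknown:
            raise ConfigurationError(f"unknown trait name(s): {', '.join(unknown)}")
        for d in self.preprocessing:
            _check_scope(d.scope)
            if d.pixels_per_cm is not None and not d.pixels_per_cm > 0:
                raise ConfigurationError("pixels_per_cm must be positive")
        if not any(s.scope == "global" for s in self.segmentation):
            raise ConfigurationError("a global segmentation parameter set is required")
        for s in self.segmentation:
            _check_scope(s.scope)
            s.params.validate()

    # field-wise directive resolution, most specific scope wins per field
    def resolve_preprocessing(self, image: GrayImage) -> PreprocessDirective:
        crop = rotation = scale = None
        for rank in (0, 1, 2):
            for d in self.preprocessing:
                if _scope_rank(d.scope, image) == rank:
                    crop = d.crop if d.crop is not None else crop
                    rotation = d.rotation_deg if d.rotation_deg is not None else rotation
                    scale = d.pixels_per_cm if d.pixels_per_cm is not None else scale
        return PreprocessDirective(scope="resolved", crop=crop,
                                   rotation_deg=rotation, pixels_per_cm=scale)

    def resolve_segmentation(self, image: GrayImage) -> SegmentationParams:
        best, best_rank = None, -1
        for s in self.segmentation:
            rank = _scope_rank(s.scope, image)
            if rank is not None and rank > best_rank:
                best, best_rank = s.params, rank
        return best  # validate() guarantees a global entry exists


@dataclass
class ImageResult:
    """Per-image manifest entry."""

    image_id: str
    stack_id: str
    status: str  # "ok" | "error"
    message: str = ""
    artifacts: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    """One entry per input image plus the exact configuration snapshot."""

    entries: list[ImageResult]
    config_xml: str
    version: str = __version__

    @property
    def n_errors(self) -> int:
        return sum(1 for e in self.entries if e.status == "error")

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "entries": [
                    {"image": e.image_id, "stack": e.stack_id, "status": e.status,
                     "message": e.message, "artifacts": e.artifacts}
                    for e in self.entries
                ],
                "config_xml": self.config_xml,
            },
            indent=2,
        )


def _process_one(
    image: GrayImage,
    config: PipelineConfig,
    registry,
    out: Path | None,
) -> tuple[TraitRecord | None, ImageResult]:
    from . import raster_io

    entry = ImageResult(image.image_id, image.stack_id, "ok")
    try:
        directive = config.resolve_preprocessing(image)
        pre = raster_io.preprocess(image, crop=directive.crop,
                                   rotation_deg=directive.rotation_deg)
        if directive.pixels_per_cm is not None:
            pre.scale = directive.pixels_per_cm
        mask = segment(pre, config.resolve_segmentation(image))
        stem = image.image_id or "image"
        if out is not None and config.export_preprocessed:
            path = out / f"{stem}.preprocessed.png"
            write_png(path, pre.pixels)
            entry.artifacts.append(str(path))
        if out is not None and config.export_mask:
            path = out / f"{stem}.mask.png"
            write_png(path, mask.pixels)
            entry.artifacts.append(str(path))
        if out is not None and config.export_skeleton and mask.pixels.any():
            path = out / f"{stem}.skeleton.png"
            write_png(path, overlay(mask, medial_axis(mask)))
            entry.artifacts.append(str(path))
        record = compute_traits(mask, selected=set(config.traits),
                                image_id=image.image_id, stack_id=image.stack_id,
                                registry=registry)
        # preserve the configured trait order
        record.values = {t: record.values[t] for t in config.traits}
        return record, entry
    except RootArchError as exc:
        entry.status = "error"
        entry.message = f"{type(exc).__name__}: {exc}"
        return None, entry


def run(
    config: PipelineConfig,
    images: Sequence[GrayImage],
    registry=None,
    progress: Callable[[str], None] | None = None,
) -> tuple[list[TraitRecord | None], RunManifest]:
    """Run the full pipeline over a batch of images.

    Returns one trait record per input image (``None`` where that image
    failed) in input order, plus the run manifest.  Results are
    byte-identical whatever ``config.workers`` is.
    """
    from .plugins import get_default_registry

    config.validate(registry)
    reg = registry if registry is not None else get_default_registry()
    out: Path | None = None
    if config.output_folder and (
        config.export_preprocessed or config.export_mask or config.export_skeleton
    ):
        out = Path(config.output_folder)
        out.mkdir(parents=True, exist_ok=True)

    def work(image: GrayImage):
        result = _process_one(image, config, reg, out)
        if progress is not None:
            _, entry = result
            progress(f"{entry.image_id}: {entry.status}"
                     + (f" ({entry.message})" if entry.message else ""))
        return result

    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(work, images))  # map preserves input order
    else:
        results = [work(img) for img in images]
    records = [r for r, _ in results]
    manifest = RunManifest(entries=[e for _, e in results],
                           config_xml=save_config(config).decode())
    return records, manifest


# -- CSV output ---------------------------------------------------------


def _render(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return format(value, ".10g")


def export_csv(
    records: Sequence[TraitRecord | None],
    path,
    trait_names: Sequence[str] | None = None,
    dimensions: dict[str, str] | None = None,
) -> None:
    """Write trait records as CSV with fixed decimal rendering.

    Header: image, stack, units, then one column per trait annotated
    with its unit (derived from the records' shared units flag; mixed
    flags fall back to the bare trait name).  Failed images (``None``
    records) are skipped — their story lives in the manifest.
    """
    rows = [r for r in records if r is not None]
    if trait_names is None:
        if not rows:
            raise ConfigurationError("trait_names is required for an empty table")
        trait_names = list(rows[0].values)
    flags = {r.units for r in rows}
    units_flag = flags.pop() if len(flags) == 1 else None

    def header(name: str) -> str:
        if units_flag is None:
            return name
        dim = TRAITS[name].dimension if name in TRAITS else (
            (dimensions or {}).get(name, "ratio"))
        return f"{name} ({unit_label(name, units_flag, dim)})"

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["image", "stack", "units"] + [header(t) for t in trait_names])
    for r in rows:
        writer.writerow(
            [r.image_id, r.stack_id, r.units]
            + [(_render(r.values[t]) if t in r.values else "") for t in trait_names]
        )
    Path(path).write_text(buf.getvalue())


# -- XML configuration --------------------------------------------------


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # repr round-trips exactly
    return str(value)


def save_config(config: PipelineConfig) -> bytes:
    """Serialize a configuration to canonical XML bytes."""
    root = etree.Element("project", version=__version__)
    pre = etree.SubElement(root, "preprocessing")
    for d in config.preprocessing:
        el = etree.SubElement(pre, "directive", scope=d.scope)
        if d.rotation_deg is not None:
            el.set("rotation_deg", _fmt(float(d.rotation_deg)))
        if d.pixels_per_cm is not None:
            el.set("pixels_per_cm", _fmt(float(d.pixels_per_cm)))
        if d.crop is not None:
            etree.SubElement(el, "crop", row0=str(d.crop.row0), col0=str(d.crop.col0),
                             n_rows=str(d.crop.n_rows), n_cols=str(d.crop.n_cols))
    seg = etree.SubElement(root, "segmentation")
    for s in config.segmentation:
        p = s.params
        etree.SubElement(
            seg, "params", scope=s.scope, algorithm=p.algorithm,
            threshold_value=_fmt(float(p.threshold_value)),
            block_size=str(p.block_size), mean_shift=_fmt(float(p.mean_shift)),
            neighborhood_size=str(p.neighborhood_size),
            bound_drop=_fmt(float(p.bound_drop)),
            min_component_size=str(p.min_component_size),
            invert_polarity=_fmt(p.invert_polarity),
        )
    tr = etree.SubElement(root, "traits")
    for name in config.traits:
        etree.SubElement(tr, "trait", name=name)
    output = etree.SubElement(root, "output", folder=config.output_folder,
                              workers=str(config.workers))
    etree.SubElement(output, "intermediates",
                     preprocessed=_fmt(config.export_preprocessed),
                     mask=_fmt(config.export_mask),
                     skeleton=_fmt(config.export_skeleton))
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def write_config(config: PipelineConfig, path) -> None:
    Path(path).write_bytes(save_config(config))


def _bool(text: str, element) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ConfigurationError(
        f"expected 'true' or 'false' at line {element.sourceline}, got {text!r}"
    )


def _reject_unknown(element, allowed_children: set[str],
                    allowed_attrs: set[str]) -> None:
    for child in element:
        if child.tag not in allowed_children:
            raise ConfigurationError(
                f"unknown element <{child.tag}> inside <{element.tag}> "
                f"at line {child.sourceline}"
            )
    for attr in element.attrib:
        if attr not in allowed_attrs:
            raise ConfigurationError(
                f"unknown attribute {attr!r} on <{element.tag}> "
                f"at line {element.sourceline}"
            )


def load_config(source, registry=None) -> PipelineConfig:
    """Parse a configuration XML file, path or bytes.

    Unknown elements, attributes, algorithm names and trait names are
    rejected with the offending location.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(str(source)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ConfigurationError(f"cannot parse configuration XML: {exc}") from exc
    if root.tag != "project":
        raise ConfigurationError(f"expected <project> root, got <{root.tag}>")
    _reject_unknown(root, {"preprocessing", "segmentation", "traits", "output"},
                    {"version"})

    config = PipelineConfig(preprocessing=[], segmentation=[], traits=[])
    for section in root:
        if section.tag == "preprocessing":
            _reject_unknown(section, {"directive"}, set())
            for el in section:
                _reject_unknown(el, {"crop"},
                                {"scope", "rotation_deg", "pixels_per_cm"})
                crop = None
                for c in el:
                    _reject_unknown(c, set(), {"row0", "col0", "n_rows", "n_cols"})
                    crop = CropRect(int(c.get("row0")), int(c.get("col0")),
                                    int(c.get("n_rows")), int(c.get("n_cols")))
                rot = el.get("rotation_deg")
                scale = el.get("pixels_per_cm")
                config.preprocessing.append(PreprocessDirective(
                    scope=el.get("scope", "global"), crop=crop,
                    rotation_deg=float(rot) if rot is not None else None,
                    pixels_per_cm=float(scale) if scale is not None else None,
                ))
        elif section.tag == "segmentation":
            _reject_unknown(section, {"params"}, set())
            for el in section:
                _reject_unknown(el, set(), {
                    "scope", "algorithm", "threshold_value", "block_size",
                    "mean_shift", "neighborhood_size", "bound_drop",
                    "min_component_size", "invert_polarity"})
                algorithm = el.get("algorithm", "global")
                if algorithm not in ALGORITHMS:
                    raise ConfigurationError(
                        f"unknown segmentation algorithm {algorithm!r} "
                        f"at line {el.sourceline}")
                params = SegmentationParams(
                    algorithm=algorithm,
                    threshold_value=float(el.get("threshold_value", "150.0")),
                    block_size=int(el.get("block_size", "19")),
                    mean_shift=float(el.get("mean_shift", "-1.25")),
                    neighborhood_size=int(el.get("neighborhood_size", "15")),
                    bound_drop=float(el.get("bound_drop", "5.0")),
                    min_component_size=int(el.get("min_component_size", "4000")),
                    invert_polarity=_bool(el.get("invert_polarity", "false"), el),
                )
                config.segmentation.append(
                    ScopedSegmentation(params, scope=el.get("scope", "global")))
        elif section.tag == "traits":
            _reject_unknown(section, {"trait"}, set())
            known = set(TRAIT_NAMES)
            if registry is not None:
                known |= set(registry.trait_names())
            for el in section:
                _reject_unknown(el, set(), {"name"})
                name = el.get("name")
                if name not in known:
                    raise ConfigurationError(
                        f"unknown trait {name!r} at line {el.sourceline}")
                config.traits.append(name)
        elif section.tag == "output":
            _reject_unknown(section, {"intermediates"}, {"folder", "workers"})
            config.output_folder = section.get("folder", "rootarch_out")
            config.workers = int(section.get("workers", "1"))
            for el in section:
                _reject_unknown(el, set(), {"preprocessed", "mask", "skeleton"})
                config.export_preprocessed = _bool(el.get("preprocessed", "false"), el)
                config.export_mask = _bool(el.get("mask", "false"), el)
                config.export_skeleton = _bool(el.get("skeleton", "false"), el)
    if not config.segmentation:
        config.segmentation = [ScopedSegmentation(SegmentationParams())]
    if not config.traits:
        config.traits = list(TRAIT_NAMES)
    config.validate(registry)
    return config
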