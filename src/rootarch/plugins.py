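"""Plugin registry and dependency-driven pipeline assembly.

The processing pipeline is a graph of named *data types* connected by
*transformations*.  Every transformation — including each bundled
segmentation algorithm and every core trait — is a plugin declaring the
data types it consumes and produces; data types are the only channel
through which plugins communicate.  New traits or algorithms therefore
drop in without touching the core: register a descriptor (in code or by
placing a manifest + implementation in a plugins folder) and the trait
becomes selectable in configurations, listed by ``rootarch
list-traits`` and written to the CSV.

Built-in data types:

- ``raw_image`` / ``preprocessed_image`` — grayscale rasters
- ``segmented_mask`` — boolean foreground mask
- ``skeleton`` — medial axis with local radii
- ``row_counts`` — per-row root crossing counts
- ``trait:<name>`` — one scalar trait value

``resolve`` turns a set of requested data types into a topologically
ordered plan in which each type is computed exactly once.  Where
several plugins produce the same type (algorithm variants of one slot),
an explicit preference selects one; otherwise ties break
deterministically by plugin name.
"""

from __future__ import annotations

import importlib.util
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .errors import CycleError, DependencyError, RegistrationError

__all__ = [
    "BUILTIN_TYPES",
    "PluginDescriptor",
    "Registry",
    "get_default_registry",
    "load_plugin_dir",
]

BUILTIN_TYPES = frozenset(
    {"raw_image", "preprocessed_image", "segmented_mask", "skeleton", "row_counts"}
)

#: An implementation maps a context dict (data-type name -> value) and
#: keyword parameters to a dict of the data types it produces.
Implementation = Callable[..., dict]


@dataclass(frozen=True)
class PluginDescriptor:
    """Declaration of one transformation plugin.

    ``consumes``/``produces`` are sets of data-type names; ``produces``
    must be non-empty and every consumed type must already be known to
    the registry (built-in or produced by a registered plugin).
    """

    name: str
    consumes: frozenset
    produces: frozenset
    parameters: dict = field(default_factory=dict)  # name -> default
    documentation: str = ""
    illustration: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "consumes", frozenset(self.consumes))
        object.__setattr__(self, "produces", frozenset(self.produces))


class Registry:
    """Holds plugin descriptors, implementations and the data-type graph."""

    def __init__(self):
        self._plugins: dict[str, tuple[PluginDescriptor, Implementation]] = {}
        self._producers: dict[str, list[str]] = {}  # type -> plugin names
        self._trait_dimensions: dict[str, str] = {}

    # -- registration ------------------------------------------------

    def known_types(self) -> set:
        return set(BUILTIN_TYPES) | set(self._producers)

    def register(
        self,
        descriptor: PluginDescriptor,
        implementation: Implementation,
        trait_dimensions: dict[str, str] | None = None,
    ) -> PluginDescriptor:
        """Register a plugin; returns the descriptor on success.

        ``trait_dimensions`` optionally maps produced trait names to a
        physical dimension (length/area/volume/ratio/...) so the scale
        conversion knows how to treat them.
        """
        if descriptor.name in self._plugins:
            raise RegistrationError(f"duplicate plugin name {descriptor.name!r}")
        if not descriptor.produces:
            raise RegistrationError(
                f"plugin {descriptor.name!r} must produce at least one data type"
            )
        unknown = descriptor.consumes - self.known_types()
        if unknown:
            raise RegistrationError(
                f"plugin {descriptor.name!r} consumes unknown data type(s): "
                f"{', '.join(sorted(unknown))}"
            )
        self._plugins[descriptor.name] = (descriptor, implementation)
        for t in descriptor.produces:
            self._producers.setdefault(t, []).append(descriptor.name)
            self._producers[t].sort()
        if trait_dimensions:
            self._trait_dimensions.update(trait_dimensions)
        return descriptor

    # -- introspection -----------------------------------------------

    def descriptors(self) -> list[PluginDescriptor]:
        return [d for d, _ in self._plugins.values()]

    def descriptor(self, name: str) -> PluginDescriptor:
        try:
            return self._plugins[name][0]
        except KeyError:
            raise DependencyError(f"no plugin named {name!r}") from None

    def trait_names(self) -> list[str]:
        """All trait names any registered plugin can produce."""
        return sorted(
            t.split(":", 1)[1] for t in self._producers if t.startswith("trait:")
        )

    def trait_dimensions(self) -> dict[str, str]:
        return dict(self._trait_dimensions)

    # -- planning and execution ---------------------------------------

    def resolve(
        self,
        requested: set,
        available: set | None = None,
        prefer: dict | None = None,
    ) -> list[str]:
        """Topologically ordered plugin plan computing every requested type.

        ``available`` lists data types already in hand (default: the
        raw image only).  ``prefer`` maps a data-type name to the plugin
        that should produce it when several candidates exist; otherwise
        the alphabetically first candidate wins.
        """
        have = set(available) if available is not None else {"raw_image"}
        prefer = prefer or {}
        plan: list[str] = []
        planned: set[str] = set()
        visiting: list[str] = []

        def producer_of(dtype: str) -> str:
            candidates = self._producers.get(dtype, [])
            if not candidates:
                raise DependencyError(
                    f"no plugin produces required data type {dtype!r}"
                )
            choice = prefer.get(dtype)
            if choice is not None:
                if choice not in candidates:
                    raise DependencyError(
                        f"plugin {choice!r} does not produce {dtype!r}"
                    )
                return choice
            return candidates[0]

        def visit(dtype: str) -> None:
            if dtype in have:
                return
            name = producer_of(dtype)
            if name in planned:
                return
            if name in visiting:
                cycle = " -> ".join(visiting[visiting.index(name):] + [name])
                raise CycleError(f"cyclic plugin dependencies: {cycle}")
            visiting.append(name)
            desc = self._plugins[name][0]
            for needed in sorted(desc.consumes):
                visit(needed)
            visiting.pop()
            planned.add(name)
            plan.append(name)
            have.update(desc.produces)

        for dtype in sorted(requested):
            visit(dtype)
        return plan

    def run_plan(self, plan: list[str], context: dict, params: dict | None = None) -> dict:
        """Execute a plan, threading data types through a context dict.

        ``params`` maps plugin name to keyword arguments overriding the
        descriptor's parameter defaults.
        """
        context = dict(context)
        params = params or {}
        for name in plan:
            desc, impl = self._plugins[name]
            kwargs = dict(desc.parameters)
            kwargs.update(params.get(name, {}))
            produced = impl(context, **kwargs)
            missing = desc.produces - set(produced)
            if missing:
                raise DependencyError(
                    f"plugin {name!r} failed to produce {', '.join(sorted(missing))}"
                )
            context.update(produced)
        return context


# -- manifest-based discovery -----------------------------------------


def _load_implementation(manifest_path: Path, manifest: dict) -> Implementation:
    module_file = manifest_path.parent / manifest["module"]
    if not module_file.exists():
        raise RegistrationError(f"plugin module not found: {module_file}")
    spec = importlib.util.spec_from_file_location(
        f"rootarch_plugin_{manifest_path.stem}", module_file
    )
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    entry = manifest.get("entry", "apply")
    try:
        return getattr(module, entry)
    except AttributeError:
        raise RegistrationError(
            f"plugin module {module_file} has no attribute {entry!r}"
        ) from None


def load_plugin_dir(registry: Registry, folder: str | Path) -> list[PluginDescriptor]:
    """Discover and register plugins from a folder of manifest files.

    Each ``*.json`` manifest declares ``name``, ``consumes``,
    ``produces``, optional ``params``, ``doc``, ``dimensions`` and the
    ``module`` (a Python file next to the manifest) whose ``entry``
    callable (default ``apply``) implements the transformation.
    """
    folder = Path(folder)
    registered = []
    for manifest_path in sorted(folder.glob("*.json")):
        manifest = json.loads(manifest_path.read_text())
        desc = PluginDescriptor(
            name=manifest["name"],
            consumes=frozenset(manifest.get("consumes", [])),
            produces=frozenset(manifest["produces"]),
            parameters=manifest.get("params", {}),
            documentation=manifest.get("doc", ""),
            illustration=manifest.get("illustration"),
        )
        impl = _load_implementation(manifest_path, manifest)
        registry.register(desc, impl, trait_dimensions=manifest.get("dimensions"))
        registered.append(desc)
    return registered


# -- core plugins ------------------------------------------------------


def _register_core(reg: Registry) -> None:
    from . import raster_io, segmentation, skeleton, traits

    def preprocess_impl(ctx, crop=None, rotation_deg=None):
        img = raster_io.preprocess(ctx["raw_image"], crop=crop, rotation_deg=rotation_deg)
        return {"preprocessed_image": img}

    reg.register(
        PluginDescriptor(
            "preprocess",
            consumes={"raw_image"},
            produces={"preprocessed_image"},
            parameters={"crop": None, "rotation_deg": None},
            documentation="Crop then rotate the raw image; scale metadata carried through.",
        ),
        preprocess_impl,
    )

    def _make_segmenter(algorithm):
        def impl(ctx, **kwargs):
            p = segmentation.SegmentationParams(algorithm=algorithm, **kwargs)
            return {"segmented_mask": segmentation.segment(ctx["preprocessed_image"], p)}
        return impl

    seg_doc = {
        "global": "Global thresholding at a fixed critical intensity.",
        "adaptive": "Local-mean thresholding over centred square blocks.",
        "double_adaptive": "Growing-square mean-drop thresholding.",
    }
    seg_params = {
        "global": {"threshold_value": 150.0, "min_component_size": 4000,
                   "invert_polarity": False},
        "adaptive": {"mean_shift": -1.25, "block_size": 19,
                     "min_component_size": 4000, "invert_polarity": False},
        "double_adaptive": {"neighborhood_size": 15, "bound_drop": 5.0,
                            "min_component_size": 4000, "invert_polarity": False},
    }
    for algo in segmentation.ALGORITHMS:
        reg.register(
            PluginDescriptor(
                f"segment-{algo.replace('_', '-')}",
                consumes={"preprocessed_image"},
                produces={"segmented_mask"},
                parameters=seg_params[algo],
                documentation=seg_doc[algo],
            ),
            _make_segmenter(algo),
        )

    reg.register(
        PluginDescriptor(
            "medial-axis",
            consumes={"segmented_mask"},
            produces={"skeleton"},
            documentation="Topology-preserving thinning with Euclidean radius estimates.",
        ),
        lambda ctx: {"skeleton": skeleton.medial_axis(ctx["segmented_mask"])},
    )

    reg.register(
        PluginDescriptor(
            "row-sweep",
            consumes={"segmented_mask"},
            produces={"row_counts"},
            documentation="Vertical line sweep counting root crossings per row.",
        ),
        lambda ctx: {"row_counts": traits.sweep_root_counts(ctx["segmented_mask"])},
    )

    def _trait_plugin(name, consumed, produced, fn, doc):
        def impl(ctx):
            out = fn(ctx)
            return {f"trait:{k}": v for k, v in out.items()}
        reg.register(
            PluginDescriptor(
                name,
                consumes=set(consumed),
                produces={f"trait:{t}" for t in produced},
                documentation=doc,
            ),
            impl,
            trait_dimensions={t: traits.TRAITS[t].dimension for t in produced},
        )

    _trait_plugin(
        "extent-traits", {"segmented_mask"},
        ("Ndepth", "Nwidth", "WDRatio", "NwA", "Perim", "Ldist"),
        lambda ctx: traits.extent_traits(ctx["segmented_mask"]),
        "Pixel-count and extent traits of the network mask.",
    )
    _trait_plugin(
        "convex-traits", {"segmented_mask"}, ("ConvA", "Solidity"),
        lambda ctx: traits.convex_traits(ctx["segmented_mask"]),
        "Convex hull area and solidity.",
    )
    _trait_plugin(
        "ellipse-fit", {"segmented_mask"}, ("MajA", "MinA", "AspR"),
        lambda ctx: traits.fit_ellipse(ctx["segmented_mask"]),
        "Axes of the moments-equivalent best-fitting ellipse.",
    )
    _trait_plugin(
        "sweep-count-traits", {"row_counts"}, ("MedR", "MaxR", "Bush"),
        lambda ctx: traits.count_traits(ctx["row_counts"]),
        "Median/maximum root counts and bushiness from the line sweep.",
    )
    _trait_plugin(
        "skeleton-traits", {"skeleton"},
        ("Nlen", "Width", "Nvol", "Nsurf", "SRL"),
        lambda ctx: traits.skeleton_traits(ctx["skeleton"]),
        "Length, width, volume, surface and SRL from the medial axis.",
    )


def default_registry() -> Registry:
    """A fresh registry with all core transformations registered."""
    reg = Registry()
    _register_core(reg)
    return reg


_default: Registry | None = None


def get_default_registry() -> Registry:
    """The process-wide default registry (created on first use)."""
    global _default
    if _default is None:
        _default = default_registry()
    return _default
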