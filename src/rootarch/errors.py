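"""Exception hierarchy shared by all pipeline stages.

Per-image failures (empty network, undefined bushiness, degenerate
geometry) are caught by the batch driver and recorded in the run
manifest; configuration and parameter errors abort before processing.
"""


class RootArchError(Exception):
    """Base class for all rootarch errors."""


class ParameterError(RootArchError, ValueError):
    """An algorithm parameter violates its constraints."""


class ConfigurationError(RootArchError, ValueError):
    """A pipeline configuration is invalid (unknown name, bad XML, ...)."""


class PreconditionError(RootArchError, ValueError):
    """An operation precondition was violated (e.g. crop out of bounds)."""


class EmptyNetworkError(RootArchError):
    """Segmentation produced no foreground pixels for an image."""

    def __init__(self, message: str = "empty network", image_id: str = ""):
        self.image_id = image_id
        if image_id:
            message = f"{message} (image {image_id!r})"
        super().__init__(message)


class DegenerateGeometryError(RootArchError):
    """The network geometry is too degenerate for the requested trait."""


class UndefinedBushinessError(RootArchError):
    """Bushiness MaxR/MedR is undefined because the median count is zero."""

    def __init__(self, message: str = "median root count is zero", image_id: str = ""):
        self.image_id = image_id
        if image_id:
            message = f"{message} (image {image_id!r})"
        super().__init__(message)


class RegistrationError(RootArchError):
    """A plugin could not be registered."""


class DependencyError(RootArchError):
    """No plugin chain produces a requested data type."""


class CycleError(DependencyError):
    """Plugin dependency declarations form a cycle."""


class PhantomSpecError(RootArchError):
    """A synthetic phantom specification is invalid."""
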