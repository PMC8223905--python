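"""Named exceptions raised across the pipeline.

Each error class corresponds to a distinct, recoverable failure mode a
caller may want to catch separately (e.g. a missing marker versus a unit
mismatch in a trial file).
"""


class ProswingError(Exception):
    """Base class for all package errors."""


class ConfigError(ProswingError):
    """Invalid simulation or pipeline configuration."""


class FormatError(ProswingError):
    """Malformed header or body in a trial/TRC file."""


class UnitError(ProswingError):
    """Unknown or inconsistent length unit declared in a file."""


class MissingMarkerError(ProswingError):
    """A marker required by the pipeline is absent from a trajectory set."""


class DegenerateGeometryError(ProswingError):
    """Collinear / coincident landmarks where a frame or axis is needed."""


class UntrackableSwingError(ProswingError):
    """Too many gap frames in a swing window for rigid-body tracking."""


class SeriesTooShortError(ProswingError):
    """Input series shorter than the filter's stable edge-padding length."""


class DivergentSwingError(ProswingError):
    """Forward-dynamics knee integration left the physical range."""


class InsufficientStridesError(ProswingError):
    """Fewer accepted strides than required for condition averaging."""
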