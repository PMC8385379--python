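"""Exception hierarchy for the kinematics pipeline.

Everything derives from :class:`AxialKinError` so callers can catch pipeline
failures without masking programming errors.
"""


class AxialKinError(Exception):
    """Base class for all pipeline errors."""


class FormatError(AxialKinError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(AxialKinError):
    """Data violates a structural invariant (e.g. a non-rigid transform)."""


class ConfigError(AxialKinError):
    """A chain configuration is inconsistent or incomplete."""


class ParameterError(AxialKinError, ValueError):
    """An analysis parameter is out of its valid range."""


class InsufficientMarkersError(AxialKinError):
    """Fewer than three common markers available for a rigid-body fit."""


class DegenerateGeometryError(AxialKinError):
    """Marker geometry is collinear, so a 3-D pose is unidentifiable."""


class AlignmentError(AxialKinError):
    """Two per-frame sequences that must share a time base do not."""
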