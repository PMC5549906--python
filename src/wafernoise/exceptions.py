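"""Exception hierarchy for wafernoise.

All wafernoise errors derive from :class:`WaferNoiseError` so callers can
catch the package's failures with a single except clause; the subclasses
distinguish bad files, bad parameters and degenerate geometry/statistics.
"""


class WaferNoiseError(Exception):
    """Base class for all wafernoise errors."""


class MeshFormatError(WaferNoiseError):
    """A mesh file could not be parsed (truncated, inconsistent, unknown)."""


class EmptyMeshError(WaferNoiseError):
    """A mesh has no vertices or no faces where content is required."""


class EmptyInputError(WaferNoiseError):
    """An operation received an empty collection of values."""


class EmptyResultError(WaferNoiseError):
    """A crop/ROI selection removed every vertex."""


class ParameterError(WaferNoiseError, ValueError):
    """A configuration value is outside its valid range."""


class DegenerateGeometryError(WaferNoiseError):
    """Points do not span a plane (fewer than 3, or collinear)."""


class InsufficientReplicatesError(WaferNoiseError):
    """Spread statistics (SD, CV, CI) require at least two replicates."""


class UndefinedStatisticError(WaferNoiseError):
    """A rank statistic is undefined (e.g. every observation identical)."""
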