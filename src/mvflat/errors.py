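"""Exception hierarchy.

All package errors derive from :class:`MVFlatError` so callers (and the CLI)
can distinguish data problems (:class:`FormatError`, :class:`TopologyError`,
:class:`CoverageError`) from numerical failures (:class:`MetricUndefinedError`,
:class:`DivergenceError`, :class:`DegenerateGeometryError`).
"""


class MVFlatError(Exception):
    """Base class for all mvflat errors."""


class FormatError(MVFlatError):
    """A valve file or in-memory mesh violates the data-model contract."""


class TopologyError(MVFlatError):
    """The mesh does not have the expected band/disk topology."""


class ParameterError(MVFlatError):
    """Invalid user-supplied parameter (generator spec, options, thresholds)."""


class DegenerateGeometryError(MVFlatError):
    """Geometric construction is undefined (collinear plane points, zero-length line step)."""


class MetricUndefinedError(MVFlatError):
    """A distortion metric is undefined (zero-length edge, zero-area or zero-angle triangle)."""


class DivergenceError(MVFlatError):
    """The spring relaxation diverged; retry with a smaller step size."""


class CoverageError(MVFlatError):
    """A vertex required by an operation has no parameterization."""


class LocationError(MVFlatError):
    """A query point lies outside the triangle / layout it must belong to."""
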