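"""Exception hierarchy for the gain-mapping pipeline.

Every error raised by the package derives from :class:`GeoGainError` so
callers (and the CLI) can catch pipeline failures without swallowing
programming errors.
"""


class GeoGainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GeoGainError):
    """A user-supplied parameter or field name is invalid."""


class EmptyInputError(GeoGainError):
    """An input layer contains no usable features."""


class RecordError(GeoGainError):
    """A single input record is malformed (carries the feature index)."""


class GeometryTypeError(GeoGainError):
    """A layer has the wrong geometry type (e.g. lines where polygons expected)."""


class CRSError(GeoGainError):
    """Missing, geographic-where-metric-required, or unsupported CRS."""


class DegenerateGeometryError(GeoGainError):
    """All points coincide or geometry otherwise carries no spatial structure."""


class InsufficientStructureError(GeoGainError):
    """Too few non-empty variogram bins to characterise spatial structure."""


class FitFailureError(GeoGainError):
    """Variogram fitting failed on every start; carries the empirical variogram."""

    def __init__(self, message, empirical=None):
        super().__init__(message)
        self.empirical = empirical


class KrigingError(GeoGainError):
    """Numerical failure while solving a kriging system."""


class MissingTreatmentError(GeoGainError):
    """A declared treatment label has no points."""


class HoldoutError(GeoGainError):
    """A treatment subset is too small to split into train and test."""


class EmptyRasterError(GeoGainError):
    """A raster has zero valid cells where at least one is required."""


class GridMismatchError(GeoGainError):
    """Two rasters do not share the same grid geometry or CRS."""


class EvaluationError(GeoGainError):
    """Too few usable observation/estimate pairs, or undefined correlation."""


class SimulationError(GeoGainError):
    """The synthetic-field generator was given an infeasible configuration."""
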