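"""Typed exceptions raised by the pipeline stages."""


class WheatDensityError(Exception):
    """Base class for all package errors."""


class ShapeError(WheatDensityError):
    """Input raster has the wrong number of dimensions or channels."""


class DegenerateInputError(WheatDensityError):
    """Input carries no usable signal (e.g. constant a* channel).

    The offending constant value, when meaningful, is stored in
    ``value``.
    """

    def __init__(self, message: str, value=None):
        super().__init__(message)
        self.value = value


class DetectionError(WheatDensityError):
    """Chessboard corner pattern could not be located."""


class FitError(WheatDensityError):
    """Homography fit is under-determined or rank deficient."""


class GeometryError(WheatDensityError):
    """Requested geometric operation produces an empty/invalid window."""


class RangeError(WheatDensityError):
    """Point coordinates fall outside the accumulator's rho range."""


class OrientationUndetectableError(WheatDensityError):
    """Hough accumulator carries no dominant orientation."""


class NoRowsError(WheatDensityError):
    """No row peak exceeds the prominence threshold."""


class SchemaError(WheatDensityError):
    """A required feature column is missing from the input table."""


class ConfigError(WheatDensityError):
    """Invalid pipeline configuration (e.g. zero-area counting window)."""
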