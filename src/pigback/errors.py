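"""Exception hierarchy shared by all pipeline stages."""


class PigbackError(Exception):
    """Base class for all package errors."""


class FormatError(PigbackError):
    """Malformed input file (PLY header, unsupported dialect, ...)."""


class SchemaError(PigbackError):
    """CSV feature table missing a required column."""


class ParameterError(PigbackError, ValueError):
    """Invalid parameter value or parameter/data size mismatch."""


class GeometryError(PigbackError):
    """Degenerate geometry (collinear projection, bad outline, ...)."""


class SegmentationError(PigbackError):
    """A segmentation stage could not isolate the pig."""


class DivergenceError(PigbackError):
    """Training produced non-finite loss."""


class ConfigError(PigbackError):
    """Inconsistent model or pipeline configuration."""
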