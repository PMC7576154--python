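"""Exception hierarchy.

Every error raised by the package derives from :class:`PaddlePressError`,
so callers can catch one type at the pipeline boundary.
"""


class PaddlePressError(Exception):
    """Base class for all paddlepress errors."""


class InvalidParameterError(PaddlePressError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(PaddlePressError, ValueError):
    """An on-disk artifact is malformed; message names the offending item."""


class MissingCalibrationError(PaddlePressError):
    """Image stack carries no pixel size and no override was given."""


class UnsupportedFormatError(PaddlePressError):
    """Input container is not a grayscale image stack."""


class DegenerateInputError(PaddlePressError, ValueError):
    """Geometric input has collapsed (zero length, empty, ...)."""


class NoBodyFoundError(PaddlePressError):
    """Segmentation found no region surviving the area filter."""


class SmoothingFailedError(PaddlePressError):
    """Contour smoothing produced a self-intersecting outline."""


class EmptyMaskError(PaddlePressError):
    """Rasterized mask contains no grid node."""


class InsufficientFramesError(PaddlePressError):
    """Temporal derivatives need at least three frames."""


class EmptyDomainError(PaddlePressError):
    """Every node is masked; nothing to integrate."""


class InvalidContourError(PaddlePressError, ValueError):
    """Contour is self-intersecting or otherwise unusable."""


class UnreliableSamplingError(PaddlePressError):
    """Too many surface probes landed in the undefined region."""


class InvalidAxisError(PaddlePressError, ValueError):
    """Thrust axis is not a unit vector."""


class AlignmentError(PaddlePressError, ValueError):
    """Frame-wise sequences disagree in length."""


class InvalidWindowError(PaddlePressError, ValueError):
    """Stroke window is empty or outside the sequence."""


class InvalidOffsetError(PaddlePressError, ValueError):
    """Offset curve self-intersects at the requested distance."""


class UnreliableProfileError(PaddlePressError):
    """Too many profile samples fell outside the defined region."""


class MissingMetricError(PaddlePressError, KeyError):
    """Requested metric absent from the cohort table."""


class ConfigError(PaddlePressError, ValueError):
    """Analysis configuration is invalid; message names the key."""


class PipelineStageError(PaddlePressError):
    """A pipeline stage failed; message names the stage (and frame)."""
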