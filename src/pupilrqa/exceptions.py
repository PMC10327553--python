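"""Exception hierarchy shared across the pipeline stages."""


class PupilRQAError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PupilRQAError, ValueError):
    """A generator or run specification violates its invariants."""


class EmptyTraceError(PupilRQAError, ValueError):
    """A trace contains no usable samples (e.g. both eyes fully invalid)."""


class InsufficientDataError(PupilRQAError, ValueError):
    """A series is too short for the requested operation."""


class MissingDataError(PupilRQAError, ValueError):
    """An operation that requires a gap-free series received missing samples."""


class DegenerateNormalizationError(PupilRQAError, ValueError):
    """Min-max normalization of a constant series (zero range)."""


class IncompleteDesignError(PupilRQAError, ValueError):
    """The subject x window grid handed to the ANOVA is not complete."""


class CalibrationError(PupilRQAError, RuntimeError):
    """Radius calibration could not bracket or reach the target recurrence rate."""
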