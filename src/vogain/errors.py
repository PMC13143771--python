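"""Exception hierarchy used across the package."""


class VogainError(Exception):
    """Base class for all package errors."""


class FormatError(VogainError):
    """A file does not conform to the expected CSV dialect (e.g. missing column)."""


class DataError(VogainError):
    """Structurally valid input with semantically invalid content."""


class ParameterError(VogainError, ValueError):
    """An argument or configuration value is out of its admissible range."""


class InsufficientDataError(VogainError):
    """Not enough data to compute the requested quantity."""


class AnalysisError(VogainError):
    """A pipeline stage could not produce a result (e.g. all half-cycles skipped)."""


class HeadMovementTooSmall(AnalysisError):
    """Head-velocity area below the floor; the half-cycle must be skipped."""
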