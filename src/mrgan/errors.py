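"""Exception hierarchy shared by all modules.

The CLI maps each category to a distinct process exit code.
"""

__all__ = [
    "MRGANError",
    "ConfigurationError",
    "DataError",
    "ShapeError",
    "NumericError",
    "CheckpointError",
]


class MRGANError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(MRGANError):
    """Invalid parameter, option or config-file value."""

    exit_code = 2


class DataError(MRGANError):
    """Missing, empty or inconsistent input data."""

    exit_code = 3


class ShapeError(MRGANError):
    """Array shapes incompatible with the requested operation."""

    exit_code = 4


class NumericError(MRGANError):
    """Non-finite values where finite ones are required."""

    exit_code = 5


class CheckpointError(MRGANError):
    """Unreadable or incompatible checkpoint archive."""

    exit_code = 6
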