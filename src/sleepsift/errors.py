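"""Exception hierarchy shared across the package."""


class SleepSiftError(Exception):
    """Base class for all package errors."""


class ParameterError(SleepSiftError, ValueError):
    """Invalid or out-of-range parameter value."""


class SignalTooShortError(SleepSiftError, ValueError):
    """Signal is too short for the requested decomposition."""


class LevelError(SleepSiftError, ValueError):
    """Decomposition level out of the valid range."""


class InputError(SleepSiftError, ValueError):
    """Malformed or empty input data."""


class StructureError(SleepSiftError, ValueError):
    """Inconsistent container structure (lengths, shapes, metadata)."""


class SolverError(SleepSiftError, RuntimeError):
    """Iterative solver failed to behave as contracted."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class UndefinedMetricError(SleepSiftError, ArithmeticError):
    """A performance metric has a zero denominator."""


class PlacementError(SleepSiftError, RuntimeError):
    """Could not place synthetic events under the spacing constraints."""


class FormatError(SleepSiftError, ValueError):
    """Malformed file content."""


class ChannelError(SleepSiftError, KeyError):
    """Requested channel not present in the recording."""


class SamplingError(SleepSiftError, ValueError):
    """Sampling rate incompatible with the requested operation."""
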