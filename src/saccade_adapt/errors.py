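"""Exception hierarchy for saccade-adapt."""


class SaccadeAdaptError(Exception):
    """Base class for all package errors."""


class ScheduleError(SaccadeAdaptError):
    """Inconsistent or unsatisfiable schedule configuration."""


class ValidationError(SaccadeAdaptError):
    """Malformed input file or data table."""


class FitError(SaccadeAdaptError):
    """Model fitting failed to produce a usable result."""


class KinematicsError(SaccadeAdaptError):
    """Trace too short, no detectable saccade, or undefined extrapolation."""
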