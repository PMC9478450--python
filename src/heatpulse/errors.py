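"""Exception hierarchy for heatpulse.

All package errors derive from :class:`HeatPulseError` so callers can
catch the whole family; the subclasses distinguish probe/signal faults
(which usually mean a bad cycle, not a bad run) from configuration and
numerical problems.
"""


class HeatPulseError(Exception):
    """Base class for all heatpulse errors."""


class OutOfRangeError(HeatPulseError):
    """Measured voltage outside (0, v_ref): open or shorted probe."""


class DomainError(HeatPulseError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class InsufficientBaselineError(HeatPulseError):
    """Fewer than the minimum number of pre-pulse baseline samples."""


class LowSignalError(HeatPulseError):
    """Temperature rise below the noise floor everywhere it is needed."""


class UnresolvedPeakError(HeatPulseError):
    """Downstream maximum not reached within the monitoring window."""


class BelowTmaxResolutionError(HeatPulseError):
    """Flow too slow for the Tmax method (conduction-dominated peak)."""


class NoEstimateError(HeatPulseError):
    """Both velocity methods failed for a depth/cycle."""


class ConfigError(HeatPulseError):
    """Missing or invalid configuration key."""


class ParseError(HeatPulseError):
    """Logger file unreadable at the level of the whole file."""
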