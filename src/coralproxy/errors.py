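"""Exception hierarchy for coralproxy.

All package-specific failures derive from :class:`CoralProxyError` so callers
can catch one base class; subclasses distinguish schema problems in input
tables, gaps in monthly series, chronology construction failures, and
degenerate statistical inputs.
"""


class CoralProxyError(Exception):
    """Base class for all coralproxy errors."""


class SchemaError(CoralProxyError):
    """An input table violates the expected column layout or invariants."""


class DataGapError(CoralProxyError):
    """A monthly series has a gap too long to interpolate."""


class ContiguityError(CoralProxyError):
    """An operation requiring a contiguous monthly grid received gaps."""


class ChronologyError(CoralProxyError):
    """Tie points or the age model cannot be constructed."""


class CalibrationError(CoralProxyError):
    """A proxy-SST calibration or inversion is not possible."""


class DegenerateDataError(CoralProxyError):
    """Statistical input has zero variance or too few points."""


class ConfigError(CoralProxyError):
    """A configuration value is invalid or inconsistent."""


class ResolutionError(CoralProxyError):
    """The sampling interval cannot resolve the simulated growth."""
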