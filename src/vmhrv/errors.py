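"""Exception hierarchy shared across the package."""


class VmHrvError(Exception):
    """Base class for all package-specific errors."""


class RRParseError(VmHrvError):
    """A record in an R-R interval file could not be parsed."""


class ValidationError(VmHrvError):
    """Input violates a structural invariant (e.g. non-positive interval)."""


class InsufficientDataError(VmHrvError):
    """Too little signal for the requested operation.

    ``available`` carries the usable amount (e.g. seconds of signal)."""

    def __init__(self, message, available=None):
        super().__init__(message)
        self.available = available


class UncorrectableSignalError(VmHrvError):
    """More than half of all beats are flagged; correction refused."""


class UndefinedMetricError(VmHrvError):
    """A metric is mathematically undefined for this input (recorded as missing)."""


class TargetNotReachedError(VmHrvError):
    """A ramp test ran out of data before the target heart rate was reached."""

    def __init__(self, message, last_stage_spm=None):
        super().__init__(message)
        self.last_stage_spm = last_stage_spm


class DesignError(VmHrvError):
    """The repeated-measures design is unbalanced or otherwise unusable."""


class DegenerateRanksError(VmHrvError):
    """All observations tied; rank-based statistics are undefined."""


class GateRefusalError(VmHrvError):
    """A gated analysis step (e.g. post-hoc tests) refused to run.

    ``reason`` is a machine-readable tag."""

    def __init__(self, message, reason=None):
        super().__init__(message)
        self.reason = reason


class ConfigError(VmHrvError):
    """A generator or pipeline configuration is infeasible."""
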