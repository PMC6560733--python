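"""Exception hierarchy for the wahr package."""


class WahrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WahrError, ValueError):
    """Invalid input data or configuration (bad row, weight-length mismatch, ...)."""


class NonEstimableError(WahrError):
    """An estimator could not produce a value (too few events, zero hazard, ...)."""


class DegenerateTestError(WahrError):
    """A test statistic is undefined (no events, zero total variance)."""


class SimulationError(WahrError):
    """Inverse-hazard sampling failed; parameters are reported in the message."""
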