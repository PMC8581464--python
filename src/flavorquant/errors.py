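"""Exception hierarchy for the quantitation pipeline.

Signals (below/over range) are exceptions on purpose: an out-of-range
inverse prediction must never flow downstream as a silent number.
"""


class FlavorQuantError(Exception):
    """Base class for all package errors."""


class PanelLoadError(FlavorQuantError):
    """Panel-definition file is missing, malformed or incomplete."""


class ArgumentError(FlavorQuantError, ValueError):
    """A scalar argument violates its contract (non-positive m/z, RT, ...)."""


class FitError(FlavorQuantError):
    """Calibration fit is impossible (rank deficiency, too few points)."""


class BelowRangeSignal(FlavorQuantError):
    """Inverse prediction fell below zero: report BLOQ, not a number."""

    def __init__(self, value: float):
        super().__init__(f"back-calculated concentration {value:g} below zero (BLOQ)")
        self.value = value


class OverRangeSignal(FlavorQuantError):
    """Response above the admissible branch of the calibration curve."""

    def __init__(self, message: str, estimate: float | None = None):
        super().__init__(message)
        self.estimate = estimate


class EmptyRangeError(FlavorQuantError):
    """No calibration level met the working-range acceptance criteria."""


class ConfigError(FlavorQuantError):
    """Experiment or run configuration is inconsistent."""
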