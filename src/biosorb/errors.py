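"""Typed exceptions used across the biosorb pipeline.

Every stage raises a subclass of :class:`BiosorbError` so callers (and the
CLI) can distinguish bad inputs (exit code 1) from fit failures (exit code 2).
"""


class BiosorbError(Exception):
    """Base class for all biosorb errors."""


class InvalidInputError(BiosorbError, ValueError):
    """An argument violates a documented precondition (e.g. Ci <= 0)."""


class DegenerateInputError(InvalidInputError):
    """Input is syntactically valid but carries no information to fit
    (fewer than two distinct calibration concentrations, all-zero
    adsorption, all-zero equilibrium concentrations, ...)."""


class InvalidCurveError(BiosorbError, ValueError):
    """A calibration curve cannot be inverted (zero slope)."""


class FitFailureError(BiosorbError, RuntimeError):
    """The optimizer did not converge. Carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PerfectFitError(BiosorbError, ArithmeticError):
    """Residual sum of squares is exactly zero, so the model selection
    criterion is undefined (infinite). Raised instead of silently emitting
    non-finite numbers into reports."""


class ConfigError(BiosorbError, ValueError):
    """A generator or pipeline configuration is inconsistent."""
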