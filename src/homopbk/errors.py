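"""Exception hierarchy for homopbk.

All package errors derive from :class:`HomopbkError` so callers can catch
one base class. Validation failures name the offending field.
"""


class HomopbkError(Exception):
    """Base class for all homopbk errors."""


class ValidationError(HomopbkError, ValueError):
    """A parameter set violates its documented invariants."""


class RangeError(ValidationError):
    """A numeric field is outside its admissible range."""


class UnsupportedOperationError(HomopbkError):
    """Operation not defined for this configuration (e.g. BMI for a rat)."""


class ConstructionError(HomopbkError):
    """Model wiring is inconsistent and the ODE system cannot be assembled."""


class SimulationError(HomopbkError):
    """The ODE/PDE integrator failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class CalibrationError(HomopbkError):
    """A root search could not bracket or reach its target."""

    def __init__(self, message: str, bracket: tuple | None = None):
        super().__init__(message)
        self.bracket = bracket


class FitError(HomopbkError):
    """Parameter identification failed for every candidate draw."""
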