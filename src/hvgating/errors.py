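"""Exception types raised by measurement and fitting routines."""

__all__ = [
    "FitFailureError",
    "NoBracketError",
    "NotActivatedError",
    "UndefinedPointError",
]


class FitFailureError(RuntimeError):
    """A least-squares fit failed to converge.

    Carries residual diagnostics in ``details`` where available.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class NoBracketError(ValueError):
    """A zero-crossing search found no sign change in the data."""


class NotActivatedError(ValueError):
    """Tail currents never exceeded the detection threshold."""


class UndefinedPointError(ValueError):
    """Conductance is undefined: the voltage lies at/near the reversal potential."""
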