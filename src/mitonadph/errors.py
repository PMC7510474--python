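"""Exception types shared across the package."""


class PreconditionError(ValueError):
    """An input violates a documented precondition (e.g. negative concentration)."""


class ConfigurationError(ValueError):
    """A configuration value is missing, unknown, or inconsistent."""


class CalibrationError(ValueError):
    """A sensor calibration is unusable (e.g. r_max <= r_min)."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class FittingError(RuntimeError):
    """Parameter estimation failed to produce a converged solution."""


class SteadyStateError(RuntimeError):
    """No admissible (non-negative) steady state could be located."""
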