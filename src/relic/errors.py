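"""Exception hierarchy shared across the package."""


class RelicError(Exception):
    """Base class for all package-specific errors."""


class InputError(RelicError, ValueError):
    """A caller supplied an invalid value (negative concentration, bad rate, ...)."""


class ConfigurationError(RelicError, ValueError):
    """A model or run configuration is structurally inconsistent."""


class DomainError(RelicError, ValueError):
    """A quantity was requested outside the domain where it is defined."""


class SimulationError(RelicError, RuntimeError):
    """The integrator failed; carries the last valid state for diagnosis."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class FixtureError(RelicError, RuntimeError):
    """Rejection sampling could not satisfy the requested constraints."""

    def __init__(self, message, n_rejections=0):
        super().__init__(message)
        self.n_rejections = n_rejections
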