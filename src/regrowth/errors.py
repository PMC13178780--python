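"""Exception types shared across the package."""


class RegrowthError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RegrowthError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(RegrowthError, ValueError):
    """A model, distribution, or scenario configuration is invalid."""


class IntegrationError(RegrowthError, RuntimeError):
    """The ODE solver failed; carries the last valid state when available.

    Attributes
    ----------
    last_time, last_burden : float or None
        The last accepted solver state before the failure.
    """

    def __init__(self, message, last_time=None, last_burden=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_burden = last_burden


class CurveFormatError(RegrowthError, ValueError):
    """An observed-curve file violates the CSV contract (row-numbered)."""
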