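"""Exception hierarchy for osteomac."""


class OsteomacError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OsteomacError):
    """Invalid configuration value (bad hypothesis index, negative factor, ...)."""


class DomainError(OsteomacError):
    """Model evaluated outside its domain (negative state components)."""


class HomeostasisError(OsteomacError):
    """Homeostatic replenishment underdetermined (zero baseline divisor)."""


class IntegrationError(OsteomacError):
    """Adaptive solver failed; carries the time at which integration broke down."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class DataError(OsteomacError):
    """Invalid dataset content (zero SD, missing column, duplicate keys)."""


class FitFailureError(OsteomacError):
    """All optimizer starts failed to produce a finite objective."""
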