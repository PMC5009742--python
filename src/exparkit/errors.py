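"""Exception hierarchy shared across the package."""


class ExparError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ExparError, ValueError):
    """A parameter or argument is outside its mathematical domain."""


class IngestError(ExparError, ValueError):
    """Malformed or insufficient input data (CSV, FASTA, curve)."""


class ConfigError(ExparError, ValueError):
    """Inconsistent or incomplete run configuration."""


class IntegrationError(ExparError, RuntimeError):
    """ODE integration failed; carries the last valid state reached.

    Attributes
    ----------
    last_state : SpeciesState or None
        The most recent state the integrator produced before failing.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
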