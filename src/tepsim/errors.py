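"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ``ConfigError`` -> 2, numerical failures
(:class:`IntegrationError` and friends) -> 3.
"""


class TepsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidConnectomeError(TepsimError, ValueError):
    """Structural connectivity input violates a precondition."""


class ParameterError(TepsimError, ValueError):
    """A model or hyper-parameter is outside its valid domain."""


class IntegrationError(TepsimError, RuntimeError):
    """State divergence or non-finite values during forward integration."""

    def __init__(self, message: str, time_ms: float | None = None,
                 region: int | None = None):
        super().__init__(message)
        self.time_ms = time_ms
        self.region = region


class HistoryUnderflowError(TepsimError, RuntimeError):
    """A delayed state was requested for a lag not covered by the history."""


class ConfigError(TepsimError, ValueError):
    """Invalid or inconsistent run configuration."""
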