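"""Exception hierarchy for the nvcgaba simulator."""


class NvcGabaError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(NvcGabaError):
    """A stimulus protocol is malformed (non-positive duration, unknown kind, ...)."""


class InvalidParameterError(NvcGabaError):
    """A parameter value violates its physical or structural constraint."""


class ConfigurationError(NvcGabaError):
    """A configuration could not be loaded or equilibrated."""


class IntegrationFailureError(NvcGabaError):
    """The ODE solver failed or produced non-finite state.

    Carries a dump of the last valid state for diagnosis.
    """

    def __init__(self, message: str, state_dump: dict | None = None):
        super().__init__(message)
        self.state_dump = state_dump or {}


class ComparisonError(NvcGabaError):
    """Simulated and reference traces cannot be compared (e.g. disjoint time ranges)."""
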