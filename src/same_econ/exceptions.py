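"""Exception hierarchy for the same-econ pipeline."""


class SameEconError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SameEconError, ValueError):
    """A scalar argument violates its precondition (e.g. negative count)."""


class InvalidRecordError(SameEconError, ValueError):
    """A person-wave record is internally inconsistent."""


class ConfigurationError(SameEconError, ValueError):
    """A config block is missing a required entry or holds an invalid value."""


class FitFailureError(SameEconError, RuntimeError):
    """A model fit did not converge within the iteration budget."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class DegenerateOutcomeError(SameEconError, ValueError):
    """The outcome is constant or the sample cannot identify the model."""


class SchemaError(SameEconError, ValueError):
    """Two tables that must share a layout do not."""
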