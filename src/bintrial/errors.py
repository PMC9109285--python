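"""Exception hierarchy shared across the package."""


class BintrialError(Exception):
    """Base class for all package errors."""


class ConfigError(BintrialError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class SchemaError(BintrialError):
    """A trial CSV does not conform to the canonical column schema."""


class ValidationError(BintrialError):
    """A trial table value violates a range or consistency invariant."""


class EmptyDesignError(BintrialError):
    """No completers remain after complete-case filtering."""


class DegenerateDesignError(BintrialError):
    """Design cannot identify the treatment effect (single arm present)."""


class ShapeError(BintrialError):
    """Parameter vector dimension does not match the model."""


class UsageError(BintrialError):
    """An operation was applied to draws from the wrong model kind."""


class InitializationError(BintrialError):
    """Sampler could not find a finite starting point."""


class SamplingFailureError(BintrialError):
    """A chain diverged on essentially every proposal."""


class DiagnosticUnavailableError(BintrialError):
    """Requested diagnostic needs more chains or draws than available."""


class SeparationError(BintrialError):
    """Likelihood is unbounded (complete or quasi-complete separation)."""
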