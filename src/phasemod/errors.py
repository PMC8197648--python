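"""Exception hierarchy shared across the pipeline."""


class PhasemodError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PhasemodError):
    """Input data violates a precondition (empty, non-finite, wrong shape)."""


class ConfigurationError(PhasemodError):
    """A parameter combination is inconsistent or out of range."""


class DegenerateInputError(PhasemodError):
    """Input is structurally valid but too degenerate for the operation."""


class IncompleteDesignError(PhasemodError):
    """The cohort table is missing cells required by the balanced design."""


class UndefinedCorrelationError(PhasemodError):
    """Correlation requested on a zero-variance signal."""
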