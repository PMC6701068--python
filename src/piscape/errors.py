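"""Exception hierarchy shared across the pipeline stages."""


class PiscapeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PiscapeError):
    """Malformed input data: bad sequence letters, unknown labels, duplicates."""


class ParameterError(PiscapeError):
    """A parameter violates an operation's precondition."""


class DegenerateInputError(PiscapeError):
    """Statistic undefined for this input (zero variance, all ties)."""


class SingularFitError(PiscapeError):
    """Rank-deficient design matrix; the family cannot be fitted."""


class InsufficientDataError(PiscapeError):
    """Too few usable data points for the requested analysis."""


class GenerationError(PiscapeError):
    """Synthetic-sequence generation failed to reach its target."""
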