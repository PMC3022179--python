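"""Exception hierarchy shared across the analysis stages."""


class SingleChanError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SingleChanError, ValueError):
    """A model or analysis parameter is outside its valid domain."""


class InsufficientDataError(SingleChanError, ValueError):
    """Too few events/points for the requested fit or statistic."""


class FitFailureError(SingleChanError, RuntimeError):
    """Nonlinear fit did not converge; carries diagnostics in args."""


class DomainError(SingleChanError, ValueError):
    """Input lies outside the mathematical domain of the operation
    (e.g. a reversal potential beyond the Nernst limits)."""


class FormatError(SingleChanError, ValueError):
    """Malformed input data (non-uniform sampling, schema mismatch)."""


class NoUnitDetectableError(SingleChanError, ValueError):
    """Automatic unit-amplitude estimation found no non-baseline mode."""
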