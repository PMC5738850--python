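"""Exception hierarchy shared across the package."""


class GpasimError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(GpasimError, ValueError):
    """A parameter is missing, ambiguous, or outside its valid domain."""


class NumericalDomainError(GpasimError, ArithmeticError):
    """An intermediate quantity left its mathematical domain by more than
    round-off tolerance (e.g. a radicand well below zero)."""


class LinearAlgebraError(GpasimError, ArithmeticError):
    """A linear solve failed or the system is too ill-conditioned to trust."""


class FormulaLookupError(GpasimError, KeyError):
    """An unknown formula identifier was requested."""


class TableFormatError(GpasimError, ValueError):
    """A serialized table does not conform to the documented dialect."""
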