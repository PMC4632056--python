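"""Exception hierarchy.

All domain violations raise :class:`DomainError` (a ``ValueError``) with a
message naming the violated bound, so batch drivers can catch one type.
"""


class HwimputeError(Exception):
    """Base class for all package errors."""


class DomainError(HwimputeError, ValueError):
    """An argument lies outside its mathematically admissible range."""


class MonomorphicMarkerError(DomainError):
    """An operation that requires a polymorphic marker received n_A = 0 or n_B = 0."""


class InestimableModelError(HwimputeError):
    """The imputation model cannot be estimated from the complete cases.

    Raised for a response without variation, covariates missing for the
    same individuals as the target, or perfect separation.
    """


class DataError(HwimputeError):
    """Input data is structurally invalid (used by the I/O layer)."""


class ParseError(DataError):
    """A cell or record could not be parsed; the message carries line/column."""
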