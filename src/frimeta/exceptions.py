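"""Exception and warning hierarchy.

All errors raised on bad user input derive from :class:`FrimetaError` so
callers can catch one base class; numerical failures during fitting derive
from :class:`NumericalError`.
"""


class FrimetaError(Exception):
    """Base class for all frimeta errors."""


class SchemaError(FrimetaError):
    """A required column is missing or the header does not match the schema."""


class ValidationError(FrimetaError):
    """A record violates a field-level constraint (type, sign, range)."""


class EmptyInputError(FrimetaError):
    """An input file or record list contained no data rows."""


class DegenerateArmError(FrimetaError):
    """A 2x2 table has an empty diseased or control arm."""


class InsufficientDataError(FrimetaError):
    """Too few studies remain for the requested model."""


class NumericalError(FrimetaError):
    """A fit failed for numerical reasons (non-finite likelihood, non-PSD
    covariance, rank-deficient design)."""


class DegenerateCurveError(NumericalError):
    """The fitted between-study variance of logit-specificity is zero, so no
    SROC curve can be traced; the summary point is still available."""


class InversionError(FrimetaError):
    """The fitted accuracy/FRI relation cannot be inverted (zero slope)."""


class PublishedValueWarning(UserWarning):
    """A packaged reference value is internally inconsistent in its source
    publication; the packaged fixture follows one variant and this warning
    names the other."""
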