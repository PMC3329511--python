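"""Exception hierarchy.

Validation problems (bad files, bad categories, contract violations) derive
from :class:`ValidationError`; numerical problems (degenerate fits, singular
designs) derive from :class:`NumericalError`.  The CLI maps the former to
exit status 2 and the latter to exit status 3.
"""


class WeantimeError(Exception):
    """Base class for all package errors."""


class ValidationError(WeantimeError):
    """Invalid input data or configuration."""


class SchemaError(ValidationError):
    """A required column or field is missing or misnamed."""


class EmptyTableError(ValidationError):
    """A trait table with no data rows."""


class AggregationError(ValidationError):
    """Conflicting categorical values within a genus being aggregated."""


class PairingError(ValidationError):
    """Two contrast sets that do not come from the same tree/node order."""


class NewickParseError(ValidationError):
    """Malformed Newick input."""


class NumericalError(WeantimeError):
    """A computation could not be carried out on the given numbers."""


class DegenerateFitError(NumericalError):
    """Zero-variance input to a regression or correlation."""


class SingularDesignError(NumericalError):
    """Rank-deficient (collinear) design matrix."""
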