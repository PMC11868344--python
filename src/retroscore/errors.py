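"""Exception hierarchy for retroscore.

All package errors derive from :class:`RetroscoreError` so callers can catch
one base class; subclasses distinguish validation problems (bad input data)
from estimation problems (a model failed to fit) and degenerate-input
conditions (an analysis is mathematically undefined on the given data).
"""


class RetroscoreError(Exception):
    """Base class for all retroscore errors."""


class FormatError(RetroscoreError):
    """A file does not have the documented structure (e.g. missing column)."""


class ValidationError(RetroscoreError):
    """Input rows violate a data-model invariant (e.g. symptom score of 3)."""


class AmbiguityError(RetroscoreError):
    """The requested operation is ambiguous (e.g. two raters, none selected)."""


class AlignmentError(RetroscoreError):
    """Two rating tables cannot be paired record-for-record."""


class UndefinedStatisticError(RetroscoreError):
    """A statistic is undefined on the given data (e.g. kappa with a
    degenerate expected-disagreement denominator)."""


class DegenerateInputError(RetroscoreError):
    """An analysis requires structure the data lack (e.g. ROC with one class)."""


class InfeasibleConstraintError(RetroscoreError):
    """No candidate threshold satisfies the requested specificity floor."""


class EstimationError(RetroscoreError):
    """A model failed to converge or could not be estimated."""


class ContrastError(RetroscoreError):
    """A Wald contrast is not estimable under the fitted model."""


class ConfigError(RetroscoreError):
    """A configuration object is internally inconsistent."""
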