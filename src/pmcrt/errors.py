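"""Exception hierarchy for pmcrt."""


class PmcrtError(Exception):
    """Base class for all pmcrt errors."""


class SchemaError(PmcrtError):
    """A mandatory column or schema entry is missing."""


class ParseError(PmcrtError):
    """A cell value could not be interpreted (carries the row number)."""


class DataError(PmcrtError):
    """A structural invariant of the dataset is violated."""


class OutcomeSpecError(PmcrtError):
    """Unknown or malformed outcome specification."""


class DegenerateSiteError(PmcrtError):
    """A site contributes no eligible respondents (or no valid expected count)."""


class WeightError(PmcrtError):
    """A site-level weight is undefined (e.g. prevalence exactly 1)."""


class InsufficientPairsError(PmcrtError):
    """Fewer than two matched pairs: no residual degrees of freedom."""


class SeparationError(PmcrtError):
    """Logistic outcome is constant (all zero or all one) — model unidentifiable."""


class FitError(PmcrtError):
    """Model fitting failed in a non-recoverable way."""


class MatchingError(PmcrtError):
    """Propensity matching cannot proceed (e.g. empty exposed set)."""


class UndefinedCVError(PmcrtError):
    """Coefficient of variation undefined (mean prevalence zero)."""


class CalibrationError(PmcrtError):
    """Requested cluster-level variability infeasible for the target prevalence."""
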