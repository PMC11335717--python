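"""Exception hierarchy shared across the package."""


class MedMRError(Exception):
    """Base class for all package errors."""


class FormatError(MedMRError):
    """Malformed input file (missing columns, non-square matrix, empty file)."""


class ValidationError(MedMRError):
    """Input violates a domain invariant (duplicate ids, out-of-range values)."""


class InsufficientInstrumentsError(MedMRError):
    """Too few instruments for the requested estimator or test."""


class DegenerateInstrumentError(MedMRError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class DegenerateDesignError(MedMRError):
    """Regression design is collinear (e.g. all exposure effects identical)."""


class ConvergenceError(MedMRError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class IrreduciblePleiotropyError(MedMRError):
    """Outlier removal exhausted the instrument set while the global
    heterogeneity test remained significant; carries the partial report."""

    def __init__(self, message, partial_report=None):
        super().__init__(message)
        self.partial_report = partial_report


class UndefinedProportionError(MedMRError):
    """Proportion mediated is undefined because the total effect is zero."""
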