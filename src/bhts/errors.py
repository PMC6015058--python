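"""Exception hierarchy shared across the package."""


class BhtsError(Exception):
    """Base class for all package errors."""


class FormatError(BhtsError):
    """A table is missing required columns or is otherwise malformed."""


class IntegrityError(BhtsError):
    """Duplicate keys, incomplete grids, or inconsistent cross-references."""


class ParseError(BhtsError):
    """A field could not be parsed (e.g. non-numeric readout)."""


class DegeneratePlateError(BhtsError):
    """A plate has zero within-plate variance where spread is required."""


class UndefinedControlWindowError(BhtsError):
    """Positive and negative control values coincide (NPI undefined)."""


class InputError(BhtsError):
    """Non-finite or otherwise invalid numeric input."""


class DegenerateResidualError(BhtsError):
    """All polish residuals are zero; the B-score denominator vanishes."""


class DegenerateScaleError(BhtsError):
    """The robust scale estimate is zero; scores are undefined."""


class ConvergenceError(BhtsError):
    """An iterative fit did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateDataError(BhtsError):
    """Dataset-level statistics are degenerate (zero variance, bad mean)."""


class ValidationError(BhtsError):
    """Hyperparameters or configuration violate an invariant."""


class UndefinedFdrError(BhtsError):
    """No well exceeds the threshold; the FDR estimate is undefined."""


class UndefinedRocError(BhtsError):
    """Truth labels contain a single class; ROC is undefined."""


class SyntheticSpecError(BhtsError):
    """A synthetic-screen specification is infeasible or inconsistent."""


class GeometryError(BhtsError):
    """Plate geometry does not match what an operation requires."""


class DecompositionError(BhtsError):
    """A scale matrix is not positive semi-definite."""


class DomainError(BhtsError):
    """A numeric argument lies outside its mathematical domain."""


class ConfigError(BhtsError):
    """A configuration file contains unknown or invalid keys."""
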