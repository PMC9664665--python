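"""Exception hierarchy for the COMPERA-BPA pipeline.

Every stage raises a subclass of :class:`ComperaError` so callers can catch
pipeline failures without masking programming errors.
"""


class ComperaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ComperaError):
    """A value is outside its admissible/physiological range, or an input
    table violates a structural invariant."""


class MissingVariable(ComperaError):
    """A variable required for scoring is absent (patients with missing
    WHO-FC, 6MWD or natriuretic peptide are excluded from scoring)."""

    def __init__(self, variable: str):
        self.variable = variable
        super().__init__(f"missing required variable: {variable}")


class EmptyScore(ComperaError):
    """Risk-score computation was requested on an empty points map."""


class RangeError(ComperaError):
    """A mean risk score lies outside the stratification policy's grid."""


class PolicyError(ComperaError):
    """Invalid stratification policy, unknown stratum label, or an attempt
    to compare policies of different granularity."""


class TimelineError(ComperaError):
    """A patient timeline is unusable (no baseline, negative event time...)."""


class EmptyCohort(ComperaError):
    """An analysis was requested on a cohort with no eligible patients."""


class GroupingError(ComperaError):
    """A group-comparison statistic needs at least two groups."""


class DegenerateSample(ComperaError):
    """A statistic is undefined on this sample (no usable pairs, constant
    vector, no events...)."""


class FitError(ComperaError):
    """A regression model failed to converge; carries the fitter's trace."""

    def __init__(self, message: str, trace: object = None):
        self.trace = trace
        super().__init__(message)


class ConfigError(ComperaError):
    """The configuration is internally inconsistent or infeasible."""


class ParseError(ComperaError):
    """An input table could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")
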