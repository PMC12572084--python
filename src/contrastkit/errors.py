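"""Exception hierarchy.

All library errors derive from :class:`ContrastError` so callers can catch one
base class.  User-input problems (bad weights, misaligned labels, malformed
data) are distinguished from degenerate statistics (zero variance, identical
rival hypotheses) because the CLI maps them to different exit codes.
"""


class ContrastError(Exception):
    """Base class for all contrastkit errors."""


class WeightError(ContrastError):
    """Invalid contrast-weight vector (non-zero sum, all zeros, bad labels)."""


class DegeneratePatternError(WeightError):
    """Predicted mean pattern is constant: no contrast can be derived."""


class DegenerateContrastError(WeightError):
    """Favored and rival contrasts coincide after standardization."""


class AlignmentError(ContrastError):
    """Weight labels do not match the condition labels in the data."""


class InsufficientDataError(ContrastError):
    """Too few observations to estimate the required variance."""


class ZeroVarianceError(ContrastError):
    """An error variance estimate is zero; the t statistic is undefined."""


class MissingCellError(ContrastError):
    """A subject is missing one or more condition measurements."""


class DomainError(ContrastError):
    """Argument outside the mathematical domain of a power function."""


class SolverError(ContrastError):
    """Sample-size search failed (target power unreachable below the cap)."""
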