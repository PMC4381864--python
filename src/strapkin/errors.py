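"""Exception hierarchy for strapkin.

Every error raised deliberately by the package derives from
:class:`StrapkinError`, so callers can catch the whole family at once.
"""


class StrapkinError(Exception):
    """Base class for all strapkin errors."""


class InvalidSpecError(StrapkinError):
    """A synthetic-geometry or generator specification is unusable
    (zero radius, non-positive rate, empty time grid, ...)."""


class GridMismatchError(StrapkinError):
    """Two curves or time series that must share a grid do not."""


class FormatError(StrapkinError):
    """A file does not contain the expected section or layout."""


class ParseError(FormatError):
    """A row inside an otherwise recognised block failed to parse.

    Carries ``line_number`` (1-based) when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class NormalizationError(StrapkinError):
    """A curve or scan cannot be area-normalised (zero or undefined area)."""


class FitDomainError(StrapkinError):
    """No overlapping non-zero region exists on which to fit."""


class DegenerateFitError(StrapkinError):
    """The fit collapsed (e.g. both mixture coefficients zero)."""


class NonIdentifiableError(StrapkinError):
    """The data carry no detectable signal change, so the kinetic
    parameters are not identifiable."""


class UndefinedStatisticError(StrapkinError):
    """A statistic's denominator vanishes (e.g. R on an all-zero curve)."""


class DomainError(StrapkinError):
    """An argument is outside the mathematical domain of the operation
    (non-positive rate, temperature below absolute zero, ...)."""
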