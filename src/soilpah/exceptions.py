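"""Exception hierarchy for the soilpah package.

Everything derives from :class:`SoilPahError` so callers can catch the
package's own failures without masking programming errors; the concrete
classes also subclass :class:`ValueError` where the failure is a bad input.
"""


class SoilPahError(Exception):
    """Base class for all soilpah errors."""


class InvalidInputError(SoilPahError, ValueError):
    """An input value violates a documented precondition."""


class EmptySeriesError(InvalidInputError):
    """A colony-appearance series contains no colonies (CD/EP undefined)."""


class EmptyGroupError(InvalidInputError):
    """A grouping/selection matched no records."""


class InvalidControlError(InvalidInputError):
    """A control value that must be strictly positive is not."""


class UndefinedCorrelationError(InvalidInputError):
    """Correlation requested on a vector with zero variance or < 3 points."""


class IncompleteDesignError(InvalidInputError):
    """A summary that requires the complete factorial design is missing cells."""


class UnbalancedDesignError(InvalidInputError):
    """The two-way ANOVA requires a balanced complete design."""


class DegenerateVarianceError(InvalidInputError):
    """Total sum of squares is zero; variance shares are undefined."""


class InvalidVarianceError(InvalidInputError):
    """A mean-square / variance parameter that must be positive is not."""


class InvalidParamsError(InvalidInputError):
    """Simulation parameters violate their invariants."""


class SchemaError(SoilPahError, ValueError):
    """A CSV input does not match the expected column schema."""


class FixtureError(SoilPahError):
    """A packaged reference table is missing or unreadable."""
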