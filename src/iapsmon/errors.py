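"""Exception hierarchy for the toolkit.

All errors derive from :class:`IapsmonError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class IapsmonError(Exception):
    """Base class for all toolkit errors."""


class InvalidGeometryError(IapsmonError, ValueError):
    """Camera/survey geometry violates a physical constraint (e.g. WD <= 0)."""


class InvalidArgumentError(IapsmonError, ValueError):
    """A scalar argument is outside its documented domain."""


class InvalidCoordinateError(IapsmonError, ValueError):
    """Latitude/longitude outside WGS84 bounds."""


class InvalidAnnotationError(IapsmonError, ValueError):
    """Degenerate or self-intersecting annotation polygon."""


class UndefinedStatisticError(IapsmonError, ValueError):
    """A statistic has no defined value (e.g. chi-square with all-zero expectations)."""


class VocabularyError(IapsmonError, ValueError):
    """A label is not part of the closed species vocabulary."""


class ConventionError(IapsmonError, ValueError):
    """A metric convention's structural precondition is not met."""


class ParseError(IapsmonError, ValueError):
    """Malformed prediction/detection file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class CannotFitError(IapsmonError, ValueError):
    """The baseline classifier was given no labelled examples to fit on."""


class CannotBalanceError(IapsmonError, ValueError):
    """Upsampling cannot proceed (a class has no images)."""


class InvalidScenarioError(IapsmonError, ValueError):
    """Synthetic survey scenario violates an invariant (e.g. zero-length road)."""


class InvalidKernelError(IapsmonError, ValueError):
    """Confusion kernel rows do not form probability distributions."""
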