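"""Exception hierarchy for funchill.

All package-specific failures derive from :class:`FunchillError` so callers
can catch one base class at the CLI boundary.
"""


class FunchillError(Exception):
    """Base class for all funchill errors."""


class ValidationError(FunchillError):
    """Input object violates a structural invariant (shape, sign, duplicates)."""


class AlignmentError(FunchillError):
    """Species labels of two inputs cannot be aligned."""

    def __init__(self, message: str, missing: tuple[str, ...] = ()):
        super().__init__(message)
        self.missing = tuple(missing)


class DegenerateDistanceError(FunchillError):
    """Quadratic entropy is zero with more than one species present, so the
    functional measures are undefined."""


class DomainError(FunchillError):
    """A parameter is outside the mathematical domain of a measure
    (e.g. negative order q, or Q >= d_max in the maximum-distance
    effective number)."""
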