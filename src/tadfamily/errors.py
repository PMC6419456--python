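"""Exception hierarchy for tadfamily.

All exceptions derive from :class:`TadFamilyError` so callers can catch the
package's failures with a single clause; each also derives from the closest
builtin (ValueError/IndexError) so generic handling keeps working.
"""


class TadFamilyError(Exception):
    """Base class for all tadfamily errors."""


class FormatError(TadFamilyError, ValueError):
    """Malformed on-disk input (shape, column count, overlap, ...)."""


class RecordError(FormatError):
    """A single bad record; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(TadFamilyError, ValueError):
    """A value outside its mathematical domain (negative contact, alpha>0, ...)."""


class BoundsError(TadFamilyError, IndexError):
    """An index outside the matrix/genome bounds."""


class EmptyInputError(TadFamilyError, ValueError):
    """No observed data where at least some is required."""


class DegenerateInputError(TadFamilyError, ValueError):
    """Input is formally valid but carries no usable information (constant matrix)."""


class ConnectivityError(TadFamilyError, ValueError):
    """Observation graph of a distance matrix is not connected."""


class InsufficientDataError(TadFamilyError, ValueError):
    """Too few usable observations for the requested statistic."""


class UndefinedCorrelationError(TadFamilyError, ValueError):
    """Correlation requested on a zero-variance vector."""
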