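"""Exception hierarchy.

Every error the library raises derives from :class:`SielkitError`, so callers
(and the CLI, which maps them to exit code 2) can catch one type.
"""


class SielkitError(Exception):
    """Base class for all sielkit errors."""


class InvalidPopulationError(SielkitError):
    """Population vector is all-zero, negative, or otherwise unusable."""


class InvalidPRError(SielkitError):
    """Participation ratio outside its valid range [1, n]."""


class EmptyEnsembleError(SielkitError):
    """An ensemble operation was given a band with no states."""


class DegenerateSchemeError(SielkitError):
    """Fragment scheme cannot support the requested descriptor (e.g. m < 2)."""


class SchemeError(SielkitError):
    """Fragment scheme is inconsistent or lacks a required fragment."""


class InvalidTemperatureError(SielkitError):
    """Non-positive temperature passed to Boltzmann weighting."""


class InvalidOverlapError(SielkitError):
    """AO overlap matrix is not symmetric positive-definite."""


class EmptyTransitionError(SielkitError):
    """Transition density carries no weight (zero matrix / zero Omega)."""


class ShapeError(SielkitError):
    """Matrix or vector dimensions disagree."""


class UnknownSubstituentError(SielkitError):
    """A ligand composition references a label absent from the table."""


class TableParseError(SielkitError):
    """A population table row or column failed validation.

    Carries ``row`` (1-based data row) and ``column`` when known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column
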