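"""Exception hierarchy for the package.

Every error raised on purpose derives from :class:`MntrdynError`, so callers
(and the CLI) can distinguish expected analysis failures from genuine bugs.
"""


class MntrdynError(Exception):
    """Base class for all package errors."""


class PdbParseError(MntrdynError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructuralMismatchError(MntrdynError):
    """Models of a multi-model file (or merged trajectories) disagree in their atom tables."""


class SelectionError(MntrdynError):
    """A selection resolved to zero atoms or is otherwise invalid."""


class CoordinateOverflowError(MntrdynError):
    """A coordinate does not fit the fixed-width PDB %8.3f field."""


class DegenerateGeometryError(MntrdynError):
    """Coincident or collinear points make an angle/dihedral/superposition undefined."""


class InsufficientDataError(MntrdynError):
    """Fewer frames/values than the operation needs."""


class DescriptorAtomError(MntrdynError):
    """An atom a descriptor needs is missing; names the atom."""


class IndexMappingError(MntrdynError):
    """A residue index falls outside the continuous-numbering map."""


class ShapeError(MntrdynError):
    """Coordinate array shapes do not match."""


class UnitError(MntrdynError):
    """Two descriptor series with incompatible units were combined."""


class WindowError(MntrdynError):
    """A time window selects no frames."""


class ParameterError(MntrdynError):
    """Invalid generator/preset/config parameters."""


class GenerationError(MntrdynError):
    """A synthetic frame could not be posed; names the frame."""
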