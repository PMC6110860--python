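"""Exception hierarchy.

Every error raised by the package derives from :class:`MscMechError` so
callers can catch the whole family; most also derive from ``ValueError``
because they signal bad inputs rather than internal failures.
"""


class MscMechError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MscMechError, ValueError):
    """An argument violates a documented precondition."""


class InvalidGeometryError(InvalidInputError):
    """A patch/pipette geometry violates its invariants."""


class DegenerateFitError(InvalidInputError):
    """Fewer than two distinct abscissa values: no slope is identifiable."""


class BaselineError(MscMechError, RuntimeError):
    """No zero-pressure prefix from which to estimate the closed-level baseline."""


class NoEventError(MscMechError, RuntimeError):
    """An idealized trace contains no channel openings."""


class NoActivationError(MscMechError, RuntimeError):
    """No channel opened during suction."""


class UndefinedConductanceError(InvalidInputError):
    """Conductance requested at zero applied voltage."""


class InsufficientDataError(InvalidInputError):
    """Too few points on one side of 0 mV for a rectification fit."""


class GeometrySolveError(MscMechError, RuntimeError):
    """The requested areal strain is unreachable for the pipette geometry."""


class TraceParseError(MscMechError, ValueError):
    """A trace/geometry/slab file is malformed; carries file and line context."""

    def __init__(self, message, path=None, line=None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


class SerializationError(MscMechError, TypeError):
    """A report entry cannot be serialized to JSON."""
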