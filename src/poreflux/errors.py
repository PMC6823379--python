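"""Exception hierarchy.

Everything raised on purpose by poreflux derives from :class:`PorefluxError`
so callers can catch package failures without swallowing programming errors.
"""


class PorefluxError(Exception):
    """Base class for all poreflux errors."""


class ParseError(PorefluxError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class StructureError(PorefluxError):
    """File content is syntactically valid but structurally inconsistent."""


class OrderingError(PorefluxError):
    """Frame times are not strictly increasing."""


class CapabilityError(PorefluxError):
    """An operation needs data (e.g. velocities) the input does not carry."""


class ConfigurationError(PorefluxError):
    """A run configuration violates an invariant of the generator/analysis."""


class ContractError(PorefluxError):
    """Inputs violate an operation's precondition."""


class DegenerateFitError(PorefluxError):
    """A regression cannot be performed (constant abscissa, too few points)."""


class WindowUnreachableError(PorefluxError):
    """Transported charge never reaches the requested event window."""

    def __init__(self, required: float, achieved: float):
        self.required = required
        self.achieved = achieved
        super().__init__(
            f"window unreachable: |Q| must reach {required:g} e "
            f"but only {achieved:g} e was transported"
        )
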