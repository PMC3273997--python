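"""Exception hierarchy shared across the package."""


class Canopy3DError(Exception):
    """Base class for all package-specific errors."""


class ParseError(Canopy3DError):
    """A file could not be parsed in the expected dialect.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where += f"{path}"
        if line is not None:
            where += f":{line}"
        super().__init__(f"{where}: {message}" if where else message)


class ValidationError(Canopy3DError):
    """A container violates one of its invariants (non-finite coordinates,
    out-of-range face indices, mismatched label length, ...)."""


class DegenerateGeometryError(Canopy3DError):
    """Input geometry does not span enough dimensions for the requested
    operation (e.g. collinear points handed to a surface triangulator)."""


class EstimationError(Canopy3DError):
    """A fitting procedure could not produce a result (too few
    correspondences, degenerate configuration, collapsed ICP pairing)."""
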