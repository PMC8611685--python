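"""Exception hierarchy for boundarydose."""


class BoundaryDoseError(Exception):
    """Base class for all package errors."""


class AlignmentError(BoundaryDoseError):
    """Grid and mask do not share one lattice."""


class EmptyStructureError(BoundaryDoseError):
    """A structure mask contains no voxels."""


class DegeneratePairedSampleError(BoundaryDoseError):
    """All paired differences are zero; the signed-rank test is undefined."""


class CoverageError(BoundaryDoseError):
    """The reference-dose generator cannot satisfy the coverage constraint."""


class PhantomGeometryError(BoundaryDoseError):
    """Requested phantom geometry is unreachable (target does not fit, or
    the lung-fraction target cannot be hit)."""


class ConfigError(BoundaryDoseError):
    """Malformed or unknown configuration content."""


class DVHParseError(BoundaryDoseError):
    """Malformed DVH exchange file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
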