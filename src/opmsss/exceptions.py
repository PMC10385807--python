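"""Exception types shared across the package."""


class OpmSssError(Exception):
    """Base class for all package-specific errors."""


class SingularPointError(OpmSssError):
    """A field was requested exactly at a singular point (e.g. the
    expansion origin of an internal term, or a dipole position)."""


class DegenerateBasisError(OpmSssError):
    """A basis column has zero norm, i.e. the array geometry cannot see
    the corresponding multipole term at all."""

    def __init__(self, l: int, m: int, kind: str):
        self.l, self.m, self.kind = l, m, kind
        super().__init__(
            f"degenerate {kind} basis column for degree l={l}, order m={m}: "
            "zero norm after projection onto the sensor array"
        )


class BasisTooLargeError(OpmSssError):
    """More basis vectors than channels where a pseudo-inverse of the full
    (or partial) basis is required."""


class InvalidDataError(OpmSssError):
    """Input data violates a precondition (non-finite values, shape
    mismatch, zero-variance ground truth, ...)."""


class InvalidConfigError(OpmSssError):
    """A study configuration is internally inconsistent."""
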