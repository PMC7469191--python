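"""Exception hierarchy for the image-to-mesh pipeline.

Every stage raises a subclass of :class:`WingforgeError` so the pipeline
driver can report which stage failed and attach a remediation hint.
"""


class WingforgeError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(WingforgeError, ValueError):
    """An input violates a documented precondition."""


class FrameMismatchError(ValidationError):
    """Primary and secondary images have different frame sizes."""


class SeedOnBorderError(ValidationError):
    """A region seed landed on a black (border) pixel."""


class OpenBoundaryError(WingforgeError):
    """A subdomain's border is not closed: its flood fill escaped to the
    image frame, so the domain geometry is not fully enclosed by black
    pixels."""


class DuplicateSeedError(ValidationError):
    """Two seeds resolve to the same connected component."""


class UnseededRegionError(WingforgeError):
    """A white connected component was reached by no burn; the user must
    seed it as a subdomain or a discontinuity."""


class DegenerateDomainError(WingforgeError):
    """The domain is too small or thin relative to h0 to mesh."""


class InpParseError(WingforgeError):
    """Malformed line in an Abaqus input deck."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
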