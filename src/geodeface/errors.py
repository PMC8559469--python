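"""Exception hierarchy with stable process exit codes.

Every error raised by the library derives from :class:`GeodefaceError` and
carries the exit code the command-line front end uses for that error class:
I/O failures exit 2, geometric/segmentation failures 3, registration or
optimizer convergence failures 4, input validation failures 5.
"""


class GeodefaceError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class VolumeIOError(GeodefaceError):
    """Unreadable or unwritable volume/points/template file."""

    exit_code = 2


class GeometryError(GeodefaceError):
    """Degenerate or inconsistent geometry (empty mask, non-nested meshes,
    grid mismatch)."""

    exit_code = 3


class SegmentationError(GeometryError):
    """Head/skull/brain segmentation could not separate tissue classes.

    ``diagnostics`` holds per-stage counts for debugging degenerate inputs.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class ConvergenceError(GeodefaceError):
    """Registration or landmark transfer did not reach a usable solution."""

    exit_code = 4


class ValidationError(GeodefaceError):
    """Input violates a documented contract (NaNs, bad labels, bad spec)."""

    exit_code = 5
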