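"""Exception taxonomy.

I/O problems and domain/geometry problems are kept distinct so the CLI can
map them to different exit codes (2 and 3 respectively).
"""


class ClausegError(Exception):
    """Base class for all package errors."""


class VolumeIOError(ClausegError):
    """A file could not be read or written as a NIfTI volume."""


class AlignmentError(ClausegError):
    """Two grids that must share shape/spacing do not."""


class EmptyMaskError(ClausegError):
    """An operation that requires a non-empty mask received an empty one."""


class DegenerateIntensityError(ClausegError):
    """Intensity clustering cannot proceed (constant or near-constant values)."""


class ProtocolError(ClausegError):
    """A diffusion acquisition protocol is invalid or insufficient for a fit."""


class CovarianceError(ClausegError):
    """A covariance-table operation received invalid input."""


class PhantomError(ClausegError):
    """A phantom specification cannot be realized on the requested grid."""
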