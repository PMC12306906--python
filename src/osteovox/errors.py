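"""Exception hierarchy.

Every error raised by the library derives from :class:`OsteovoxError`; the
command-line interface maps each subclass to a distinct exit code.
"""


class OsteovoxError(Exception):
    """Base class for all osteovox errors."""

    exit_code = 1


class UnknownSegmentError(OsteovoxError):
    """The (site, part) pair does not exist in the segment registry."""

    exit_code = 2


class NotModeledAtAgeError(OsteovoxError):
    """The segment exists but carries no active marrow at the requested age
    (a dark field in the parameter tables)."""

    exit_code = 3


class MissingDimensionsError(OsteovoxError):
    """The segment has no packaged dimensional data; ingest a size table."""

    exit_code = 4


class GeometryError(OsteovoxError):
    """Invalid shape, voxel size or cortical-shell request."""

    exit_code = 5


class DimensionTooSmallError(GeometryError):
    exit_code = 5


class ShellExceedsExtentError(GeometryError):
    exit_code = 5


class LatticeError(OsteovoxError):
    """Invalid trabecular-lattice parameters."""

    exit_code = 6


class UnreachableBvtvError(LatticeError):
    exit_code = 6


class RodThinnerThanVoxelError(LatticeError):
    exit_code = 6


class MorphometryError(OsteovoxError):
    exit_code = 7


class PhantomIOError(OsteovoxError):
    """Unreadable, corrupted or version-incompatible phantom file."""

    exit_code = 8
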