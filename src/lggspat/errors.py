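"""Exception hierarchy for lggspat.

All errors raised by this package derive from :class:`LggspatError` so
callers can catch package failures with a single handler while still
distinguishing validation problems (bad manifests, inconsistent grids)
from geometric degeneracies (empty masks, oblique affines).
"""


class LggspatError(Exception):
    """Base class for all lggspat errors."""


class ValidationError(LggspatError):
    """Invalid user input: manifest rows, config values, case metadata."""


class GridMismatchError(LggspatError):
    """Two volumes that must share a voxel grid do not."""


class EmptyMaskError(LggspatError):
    """An operation that requires foreground voxels received an empty mask."""


class DimensionalityError(LggspatError):
    """A volume on disk is not a 3D image."""


class UnsupportedGeometryError(LggspatError):
    """The affine is oblique where an axis-aligned grid is required."""


class DegenerateInputError(LggspatError):
    """Input is formally valid but carries no analyzable signal."""


class PlacementError(LggspatError):
    """Synthetic lesion placement failed after exhausting attempts."""
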