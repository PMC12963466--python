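"""Exception types shared across the package."""


class StonewinError(Exception):
    """Base class for all package-specific errors."""


class InvalidContrastError(StonewinError, ValueError):
    """Object is not denser than its background; no half-value window exists."""


class BoundsError(StonewinError, ValueError):
    """Geometry does not fit inside the voxel volume (with blur margin)."""


class EmptySlabError(StonewinError, ValueError):
    """A reformatted slab interval contains no voxel centers."""


class EmptyRoiError(StonewinError, ValueError):
    """A circular ROI contains no pixel centers."""


class NotAStoneError(StonewinError, ValueError):
    """Seed point does not sit on a supra-threshold (apparent stone) region."""


class SeparationError(StonewinError, ValueError):
    """Logistic likelihood is unbounded (complete separation)."""


class DimensionalityError(StonewinError, ValueError):
    """Input volume is not a 3D scalar grid."""
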