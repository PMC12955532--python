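"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers (and the
CLI) can report the failing stage precisely.
"""


class BiodoseError(Exception):
    """Base class for all package errors."""


class Not3DVolumeError(BiodoseError):
    """A NIfTI file did not contain a 3-D scalar volume."""


class NonPositiveSpacingError(BiodoseError):
    """A grid or header declared a voxel spacing <= 0."""


class NonAxisAlignedError(BiodoseError):
    """A NIfTI affine contains rotation/shear; only axis-aligned grids are supported."""


class GridMismatchError(BiodoseError):
    """Two maps/masks expected on the same grid live on different grids."""


class DisjointExtentError(BiodoseError):
    """Resampling target shares no physical extent with the source."""


class EmptyMaskError(BiodoseError):
    """An operation requiring a non-empty mask received an empty one."""


class EmptyReferenceError(BiodoseError):
    """The normalization reference region is empty or has non-positive mean."""


class MissingStructureError(BiodoseError):
    """A required named structure is absent from the structure set."""


class InvalidGeometryError(BiodoseError):
    """Phantom geometry violates the nesting requirements."""


class ConfigError(BiodoseError):
    """Configuration file is invalid (unknown key, bad value)."""


class StageError(BiodoseError):
    """Pipeline stage failure; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
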