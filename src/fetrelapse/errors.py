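"""Exception hierarchy shared across the package."""


class FetRelapseError(Exception):
    """Base class for all package-specific errors."""


class GridCompatibilityError(FetRelapseError):
    """Two structures live on voxel grids that do not agree."""


class DimensionalityError(FetRelapseError):
    """An image file does not have exactly three spatial dimensions."""


class VolumeFormatError(FetRelapseError):
    """An image file could not be read as NIfTI."""


class ReferenceRegionError(FetRelapseError):
    """The normal-brain reference region is empty or has non-positive mean uptake."""


class EmptyStructureError(FetRelapseError):
    """A geometric operation that requires a non-empty mask received an empty one."""


class UndefinedFractionError(FetRelapseError):
    """A coverage or overlap fraction was requested with an empty denominator mask."""


class DegenerateTestError(FetRelapseError):
    """A paired test where every difference is zero has no defined statistic."""


class FixtureIntegrityError(FetRelapseError):
    """A packaged per-patient table failed its transcription checksum."""


class PhantomConfigurationError(FetRelapseError):
    """Requested phantom geometry does not fit inside the brain or the grid."""
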