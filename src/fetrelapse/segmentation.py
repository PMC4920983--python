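"""Tumor delineation from PET and MRI.

The biological target volume is autocontoured from an amino-acid PET scan
by thresholding the tumor-to-brain ratio (TBR): each voxel's uptake divided
by the mean uptake over a user-supplied normal-brain reference region.  The
clinically validated cut-off TBR >= 1.6 separates tumoral from peritumoral
tissue and is the default threshold throughout.  The comparison is
inclusive (>=) and configurable; because TBR is a ratio, the contour is
invariant to any global rescaling of the PET image.

MRI contrast enhancement is delineated by a plain intensity threshold; this
stands in for manual gadolinium-enhancement contouring and is used on
synthetic enhancement maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ReferenceRegionError
from .grid import BinaryMask, GridSpec, ScalarVolume

#: clinically validated tumor-to-brain-ratio cut-off for FET uptake
DEFAULT_TBR_THRESHOLD = 1.6


@dataclass
class TbrMap:
    """Voxel-wise tumor-to-brain ratio (dimensionless) with its reference value."""

    grid: GridSpec
    tbr: np.ndarray
    background_reference: float

    def __post_init__(self) -> None:
        self.tbr = np.asarray(self.tbr, dtype=np.float64)
        if tuple(self.tbr.shape) != self.grid.shape:
            raise ValueError("TBR array shape does not match grid")
        if self.background_reference <= 0:
            raise ReferenceRegionError(
                f"background reference must be positive, got "
                f"{self.background_reference}"
            )


def compute_tbr(pet: ScalarVolume, background_mask: BinaryMask) -> TbrMap:
    """Divide PET uptake voxel-wise by the mean uptake in the reference region.

    Parameters
    ----------
    pet
        PET uptake map (arbitrary activity units, non-negative).
    background_mask
        Non-empty normal-brain region, e.g. contralateral healthy tissue.

    Raises
    ------
    ReferenceRegionError
        If the reference region is empty or its mean uptake is not positive.
    """
    pet.grid.require_compatible(background_mask.grid, "PET and background mask")
    if background_mask.is_empty:
        raise ReferenceRegionError("background reference mask is empty")
    reference = float(pet.values[background_mask.data].mean())
    if reference <= 0:
        raise ReferenceRegionError(
            f"mean background uptake must be positive, got {reference}"
        )
    return TbrMap(pet.grid, pet.values / reference, reference)


def autocontour_tbr(
    tbr: TbrMap,
    threshold: float = DEFAULT_TBR_THRESHOLD,
    *,
    inclusive: bool = True,
) -> BinaryMask:
    """Autocontour the biological target volume at a TBR threshold.

    Every voxel at or above the threshold is included (all connected
    components retained; no minimum-size filtering).  ``inclusive=False``
    switches to a strict > comparison for sensitivity checks.
    """
    if threshold <= 0:
        raise ValueError(f"TBR threshold must be positive, got {threshold}")
    if inclusive:
        member = tbr.tbr >= threshold
    else:
        member = tbr.tbr > threshold
    return BinaryMask(tbr.grid, member)


def enhancement_mask(mri: ScalarVolume, threshold: float) -> BinaryMask:
    """Threshold an MRI enhancement map at *threshold* (same units as the image)."""
    if not np.isfinite(threshold):
        raise ValueError("enhancement threshold must be finite")
    return BinaryMask(mri.grid, mri.values >= threshold)
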