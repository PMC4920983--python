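"""Target-volume geometry: margin expansion, overlap metrics, cavity dynamics.

Radiotherapy target volumes are built by isotropic margin expansion of a
delineated tumor mask: the clinical target volume (CTV) adds a
microscopic-spread margin to the imaged tumor, and the planning target
volume (PTV) adds a setup-uncertainty margin (5 mm by convention) around
the CTV.  Expansion is implemented with a Euclidean distance transform of
the mask complement (``scipy.ndimage.distance_transform_edt`` with
``sampling=spacing``): a voxel belongs to the expanded mask iff its centre
lies within the margin distance of some member voxel centre, which respects
anisotropic voxel spacing exactly.

Overlap and coverage metrics quantify how much of one structure lies inside
another, in ml and as a fraction of the numerator structure — the quantities
behind baseline FET/MRI overlap analysis and recurrence-coverage simulation.
Cavity dynamics summarise how the post-surgical resection cavity shrinks
(ml) and shifts (mm, centroid displacement) between baseline and relapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import EmptyStructureError, UndefinedFractionError
from .grid import BinaryMask

#: margin ladder (mm) explored by the target-volume simulation
DEFAULT_MARGIN_LADDER_MM = (0.0, 5.0, 7.0, 10.0)

#: conventional setup/immobilisation margin (mm) between CTV and PTV
DEFAULT_SETUP_MARGIN_MM = 5.0


@dataclass
class TargetStructure:
    """A CTV or PTV: a binary mask plus the margins and dose that define it."""

    label: Literal["CTV", "PTV"]
    source: Literal["FET", "MRI"]
    margin_mm: float
    mask: BinaryMask
    setup_margin_mm: float = 0.0
    nominal_dose_Gy: float | None = None

    def __post_init__(self) -> None:
        if self.margin_mm < 0 or self.setup_margin_mm < 0:
            raise ValueError("margins must be non-negative")

    @property
    def volume_ml(self) -> float:
        return self.mask.volume_ml


@dataclass
class CavityDynamics:
    """Change of the resection cavity between baseline and relapse."""

    shrinkage_ml: float  # baseline volume - relapse volume; positive = shrink
    shift_mm: float  # displacement of the cavity's representative point

    def __post_init__(self) -> None:
        if self.shift_mm < 0:
            raise ValueError("shift must be non-negative")


def volume_ml(mask: BinaryMask) -> float:
    """Mask volume in ml (voxel count x voxel volume); 0.0 for an empty mask."""
    return mask.volume_ml


def expand_margin(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Expand a mask isotropically by *margin_mm* (Euclidean, anisotropy-aware).

    The result contains exactly the voxels whose centre lies within
    ``margin_mm`` of some member voxel centre; it is always a superset of
    the input.  A margin of 0 returns the mask unchanged.

    Raises
    ------
    EmptyStructureError
        For an empty input mask — expanding nothing is undefined here.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    if mask.is_empty:
        raise EmptyStructureError("cannot expand an empty structure")
    if margin_mm == 0:
        return BinaryMask(mask.grid, mask.data.copy())
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.grid.spacing)
    # tiny relative tolerance so margins landing exactly on a voxel-centre
    # distance (e.g. 5 mm on a 1 mm grid) include that voxel despite EDT
    # floating-point rounding
    return BinaryMask(mask.grid, dist <= margin_mm * (1 + 1e-12) + 1e-9)


def build_ctv(
    source_mask: BinaryMask,
    margin_mm: float,
    brain_mask: BinaryMask | None = None,
    *,
    source: Literal["FET", "MRI"] = "FET",
    nominal_dose_Gy: float | None = None,
) -> TargetStructure:
    """Build a clinical target volume by margin expansion of a tumor mask.

    When *brain_mask* is given the expanded volume is clipped to it,
    emulating the clinical adaptation of CTVs to anatomical boundaries.
    """
    expanded = expand_margin(source_mask, margin_mm)
    if brain_mask is not None:
        expanded = expanded.intersect(brain_mask)
    return TargetStructure(
        label="CTV",
        source=source,
        margin_mm=float(margin_mm),
        mask=expanded,
        nominal_dose_Gy=nominal_dose_Gy,
    )


def build_ptv(
    ctv: TargetStructure,
    setup_margin_mm: float = DEFAULT_SETUP_MARGIN_MM,
) -> TargetStructure:
    """Add a setup-uncertainty margin around a CTV to obtain the PTV.

    ``setup_margin_mm=0`` reproduces a boost PTV defined as the CTV itself
    with no additional margin.
    """
    if setup_margin_mm == 0:
        mask = BinaryMask(ctv.mask.grid, ctv.mask.data.copy())
    else:
        mask = expand_margin(ctv.mask, setup_margin_mm)
    return TargetStructure(
        label="PTV",
        source=ctv.source,
        margin_mm=ctv.margin_mm,
        setup_margin_mm=float(setup_margin_mm),
        mask=mask,
        nominal_dose_Gy=ctv.nominal_dose_Gy,
    )


def intersection_stats(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """Intersection volume of two masks in ml and as a fraction of mask *a*.

    Raises
    ------
    UndefinedFractionError
        If *a* is empty (the fraction denominator).
    """
    if a.is_empty:
        raise UndefinedFractionError(
            "intersection fraction undefined for an empty reference mask"
        )
    inter_ml = a.intersect(b).volume_ml
    return inter_ml, inter_ml / a.volume_ml


def coverage_fraction(recurrence: BinaryMask, target: TargetStructure) -> float:
    """Fraction of the recurrence volume lying inside the target structure."""
    if recurrence.is_empty:
        raise UndefinedFractionError(
            "coverage fraction undefined for an empty recurrence mask"
        )
    return recurrence.intersect(target.mask).volume_ml / recurrence.volume_ml


def centroid(mask: BinaryMask) -> np.ndarray:
    """World coordinates (mm) of the unweighted mean of member voxel centres."""
    if mask.is_empty:
        raise EmptyStructureError("centroid of an empty mask is undefined")
    idx = np.argwhere(mask.data)
    return mask.grid.voxel_centers(idx).mean(axis=0)


def cavity_shift(cavity_baseline: BinaryMask, cavity_relapse: BinaryMask) -> float:
    """Euclidean distance (mm) between the two cavity centroids.

    The representative centre point of each cavity is operationalised as its
    centroid.
    """
    cavity_baseline.grid.require_compatible(cavity_relapse.grid, "cavity masks")
    c1 = centroid(cavity_baseline)
    c2 = centroid(cavity_relapse)
    return float(np.linalg.norm(c2 - c1))


def cavity_shrinkage(cavity_baseline: BinaryMask, cavity_relapse: BinaryMask) -> float:
    """Baseline minus relapse cavity volume in ml; positive means shrink."""
    if cavity_baseline.is_empty or cavity_relapse.is_empty:
        raise EmptyStructureError("cavity shrinkage requires two non-empty cavities")
    cavity_baseline.grid.require_compatible(cavity_relapse.grid, "cavity masks")
    return cavity_baseline.volume_ml - cavity_relapse.volume_ml


def cavity_dynamics(
    cavity_baseline: BinaryMask, cavity_relapse: BinaryMask
) -> CavityDynamics:
    """Shrinkage (ml) and centroid shift (mm) between the two cavity masks."""
    return CavityDynamics(
        shrinkage_ml=cavity_shrinkage(cavity_baseline, cavity_relapse),
        shift_mm=cavity_shift(cavity_baseline, cavity_relapse),
    )
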