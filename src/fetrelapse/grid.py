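"""Voxel-grid data model and NIfTI I/O shared by every analysis stage.

All structures in this package — PET uptake maps, MRI enhancement maps, and
the binary masks derived from them (tumor volumes, resection cavities, CTVs
and PTVs) — live on a common axis-aligned voxel grid.  The grid carries
voxel spacing in millimetres and the world position of the centre of voxel
(0,0,0); indices are 0-based and a voxel is in or out of a mask with no
partial-volume weighting, so a mask's volume in ml is simply its voxel
count times the voxel volume.

Inputs are assumed co-registered: no resampling or registration between
grids is performed, and combining structures on incompatible grids is an
error rather than an implicit interpolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    GridCompatibilityError,
    ReferenceRegionError,
    VolumeFormatError,
)

#: tolerance (mm) within which two grids are considered the same grid
GRID_TOL_MM = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Shape, spacing and origin of an axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Voxel counts along each of the three axes.
    spacing
        Voxel edge lengths in mm; all components must be positive and finite.
    origin
        World position in mm of the *centre* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise DimensionalityError("GridSpec is strictly three-dimensional")
        if any(s <= 0 for s in shape):
            raise ValueError(f"voxel counts must be positive, got {shape}")
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be positive and finite, got {spacing}")
        if not all(np.isfinite(o) for o in origin):
            raise ValueError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (dx*dy*dz / 1000)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def compatible(self, other: "GridSpec", tol: float = GRID_TOL_MM) -> bool:
        """Whether the two grids agree in shape, spacing and origin within *tol* mm."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_compatible(self, other: "GridSpec", what: str = "structures") -> None:
        if not self.compatible(other):
            raise GridCompatibilityError(
                f"{what} live on incompatible grids: {self} vs {other}"
            )

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (axis-aligned, voxel-centre convention)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self, index_array: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres for an (n, 3) index array."""
        idx = np.asarray(index_array, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class ScalarVolume:
    """A 3D scalar image (PET uptake or MRI enhancement) on a voxel grid."""

    grid: GridSpec
    values: np.ndarray
    require_nonnegative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D value array, got ndim={self.values.ndim}"
            )
        if tuple(self.values.shape) != self.grid.shape:
            raise GridCompatibilityError(
                f"value array shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")
        if self.require_nonnegative and np.any(self.values < 0):
            raise ValueError("PET uptake values must be non-negative")


@dataclass
class BinaryMask:
    """A 3D boolean structure (tumor volume, CTV/PTV, cavity) on a voxel grid."""

    grid: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask array, got ndim={self.data.ndim}"
            )
        if tuple(self.data.shape) != self.grid.shape:
            raise GridCompatibilityError(
                f"mask shape {self.data.shape} does not match grid shape "
                f"{self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    @property
    def volume_ml(self) -> float:
        """Mask volume in ml: voxel count times voxel volume."""
        return self.voxel_count * self.grid.voxel_volume_ml

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_compatible(other.grid, "masks being intersected")
        return BinaryMask(self.grid, self.data & other.data)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_compatible(other.grid, "masks being merged")
        return BinaryMask(self.grid, self.data | other.data)


@dataclass
class PatientCase:
    """One subject's co-registered baseline and relapse imaging.

    Holds the four imaging time points used throughout the analysis: PET and
    MRI at baseline (post-surgery, for treatment planning) and at relapse,
    plus the resection-cavity masks, a normal-brain background region for the
    tumor-to-brain-ratio reference, and an optional whole-brain mask used to
    clip expanded target volumes.
    """

    case_id: str
    pet_baseline: ScalarVolume
    pet_relapse: ScalarVolume
    mri_baseline: ScalarVolume
    mri_relapse: ScalarVolume
    background_mask: BinaryMask
    cavity_baseline: BinaryMask | None = None
    cavity_relapse: BinaryMask | None = None
    brain_mask: BinaryMask | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = self.pet_baseline.grid
        members = [
            ("pet_relapse", self.pet_relapse),
            ("mri_baseline", self.mri_baseline),
            ("mri_relapse", self.mri_relapse),
            ("background_mask", self.background_mask),
            ("cavity_baseline", self.cavity_baseline),
            ("cavity_relapse", self.cavity_relapse),
            ("brain_mask", self.brain_mask),
        ]
        for name, member in members:
            if member is not None:
                grid.require_compatible(member.grid, f"case {self.case_id}: {name}")
        if self.background_mask.is_empty:
            raise ReferenceRegionError(
                f"case {self.case_id}: background reference mask is empty"
            )
        if (
            self.cavity_baseline is not None
            and (self.background_mask.data & self.cavity_baseline.data).any()
        ):
            raise ValueError(
                f"case {self.case_id}: background reference region overlaps the "
                "baseline resection cavity"
            )

    @property
    def grid(self) -> GridSpec:
        return self.pet_baseline.grid


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, GridSpec]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(str(path))
        header_zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / malformed header
        raise VolumeFormatError(f"could not read NIfTI image {path}: {exc}") from exc
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions"
        )
    spacing = tuple(float(z) for z in header_zooms[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    grid = GridSpec(shape=tuple(data.shape), spacing=spacing, origin=origin)
    return data, grid


def read_volume(path: str | os.PathLike) -> ScalarVolume:
    """Read a 3D NIfTI image as a :class:`ScalarVolume`.

    Spacing is taken from the header zooms (mm) and the origin from the
    affine translation; orientation beyond that is not interpreted because
    inputs are assumed co-registered on a shared axis-aligned grid.
    """
    data, grid = _load_nifti(path)
    return ScalarVolume(grid, np.asarray(data, dtype=np.float64))


def write_volume(vol: ScalarVolume, path: str | os.PathLike) -> None:
    """Write a scalar volume as NIfTI-1, float64 so values round-trip losslessly."""
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine())
    img.header.set_zooms(vol.grid.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"could not write volume to {path}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI mask; any non-zero voxel is a member."""
    data, grid = _load_nifti(path)
    return BinaryMask(grid, np.asarray(data) != 0)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI-1 uint8 {0, 1}."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine())
    img.header.set_zooms(mask.grid.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"could not write mask to {path}: {exc}") from exc
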