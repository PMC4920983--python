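"""Synthetic paired baseline/relapse brain phantoms.

Generates the kind of co-registered imaging a post-surgical relapse-pattern
analysis consumes, without any patient data: a spherical "brain" of uniform
reference PET uptake, a resection cavity that shrinks (~12 ml) and shifts
(~6 mm) between baseline and relapse, a baseline FET-positive lesion at a
configurable tumor-to-brain-ratio level, a partially overlapping MRI
enhancement blob (~12 % of the FET volume by default), and a relapse lesion
only partially inside the baseline lesion (~39 % by default).  The shapes
are spheres, so every placement can be solved in closed form: blob offsets
are computed from the analytic sphere–sphere lens volume to hit the
configured overlap fractions, and the *achieved* fractions — recomputed
from the emitted voxel masks themselves — are reported as ground truth.

Realistic anatomy, PET projection noise and MRI physics are deliberately
out of scope; the phantom's job is to make every pipeline stage exactly
checkable.  With ``noise_sd=0`` (the default) autocontouring at the
configured TBR level recovers the ground-truth masks voxel-for-voxel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import PhantomConfigurationError
from .geometry import cavity_shift, cavity_shrinkage, intersection_stats
from .grid import BinaryMask, GridSpec, PatientCase, ScalarVolume, write_mask, write_volume

#: default phantom grid: 2 mm isotropic, 80^3 (a 16 cm cube)
DEFAULT_PHANTOM_GRID = GridSpec(shape=(80, 80, 80), spacing=(2.0, 2.0, 2.0))


def sphere_volume_ml(radius_mm: float) -> float:
    """Analytic sphere volume (4/3)*pi*r^3 in ml."""
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0


def sphere_radius_for_volume_ml(volume_ml: float) -> float:
    """Radius in mm of a sphere with the given volume in ml."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return (volume_ml * 1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def lens_volume_ml(r1_mm: float, r2_mm: float, d_mm: float) -> float:
    """Intersection volume (ml) of two spheres with centres *d_mm* apart."""
    if d_mm >= r1_mm + r2_mm:
        return 0.0
    if d_mm <= abs(r1_mm - r2_mm):
        return sphere_volume_ml(min(r1_mm, r2_mm))
    d, r, R = d_mm, min(r1_mm, r2_mm), max(r1_mm, r2_mm)
    vol_mm3 = (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * (r + R) - 3 * (r - R) ** 2)
        / (12 * d)
    )
    return vol_mm3 / 1000.0


def offset_for_overlap(
    r_fixed_mm: float, r_moving_mm: float, target_overlap_ml: float
) -> float:
    """Centre distance at which two spheres overlap by *target_overlap_ml*.

    Solved by bisection on the monotone lens-volume formula; a target of 0
    returns the tangent distance, a target at least the smaller sphere's
    volume returns full containment.
    """
    max_overlap = sphere_volume_ml(min(r_fixed_mm, r_moving_mm))
    if target_overlap_ml <= 0:
        return r_fixed_mm + r_moving_mm
    if target_overlap_ml >= max_overlap:
        return abs(r_fixed_mm - r_moving_mm)
    lo, hi = abs(r_fixed_mm - r_moving_mm), r_fixed_mm + r_moving_mm
    return float(
        brentq(lambda d: lens_volume_ml(r_fixed_mm, r_moving_mm, d) - target_overlap_ml,
               lo + 1e-9, hi - 1e-9, xtol=1e-10)
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise parameters of one synthetic baseline/relapse case.

    The defaults emulate the cohort-level structure of a post-surgical
    glioblastoma relapse analysis: cavity shrinking by ~12 ml and shifting
    by ~6 mm between time points, baseline MRI enhancement overlapping the
    FET-positive volume by ~12 % of the FET volume, and a relapse lesion
    lying ~39 % inside the baseline lesion.  Radii are chosen so that the
    emitted volumes land in the ml range of such cohorts (baseline FET
    ~11 ml, baseline MRI ~5 ml, relapse FET ~12 ml, relapse MRI ~19 ml).
    """

    grid: GridSpec = DEFAULT_PHANTOM_GRID
    brain_radius_mm: float = 60.0
    cavity_radius_baseline_mm: float = 20.0
    cavity_shrink_ml: float = 12.0
    cavity_shift_mm: float = 6.0
    fet1_radius_mm: float = 14.0
    fet1_rim_offset_mm: float = 5.0
    fet1_tbr_level: float = 2.0
    mri1_radius_mm: float = 10.5
    mri1_overlap_fraction_of_fet1: float = 0.12
    fet2_radius_mm: float = 14.2
    fet2_fraction_in_fet1: float = 0.39
    mri2_radius_mm: float = 16.6
    mri2_overlap_fraction_of_fet2: float = 0.13
    background_radius_mm: float = 8.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = (
            self.brain_radius_mm,
            self.cavity_radius_baseline_mm,
            self.fet1_radius_mm,
            self.mri1_radius_mm,
            self.fet2_radius_mm,
            self.mri2_radius_mm,
            self.background_radius_mm,
        )
        if any(r <= 0 for r in radii):
            raise PhantomConfigurationError(f"all radii must be positive, got {radii}")
        relapse_vol = (
            sphere_volume_ml(self.cavity_radius_baseline_mm) - self.cavity_shrink_ml
        )
        if relapse_vol <= 0:
            raise PhantomConfigurationError(
                "cavity_shrink_ml exceeds the baseline cavity volume"
            )
        if self.cavity_shift_mm < 0 or self.noise_sd < 0:
            raise PhantomConfigurationError("shift and noise must be non-negative")
        for frac in (
            self.mri1_overlap_fraction_of_fet1,
            self.fet2_fraction_in_fet1,
            self.mri2_overlap_fraction_of_fet2,
        ):
            if not 0.0 <= frac <= 1.0:
                raise PhantomConfigurationError(
                    f"overlap fractions must lie in [0, 1], got {frac}"
                )


@dataclass
class GroundTruth:
    """The phantom's true masks plus metrics recomputed from those masks."""

    fet1: BinaryMask
    mri1: BinaryMask
    fet2: BinaryMask
    mri2: BinaryMask
    cavity_baseline: BinaryMask
    cavity_relapse: BinaryMask
    fet1_ml: float
    mri1_ml: float
    fet2_ml: float
    mri2_ml: float
    overlap1_fraction_of_fet1: float
    overlap2_fraction_of_fet2: float
    fet2_fraction_in_fet1: float
    cavity_shift_mm: float
    cavity_shrinkage_ml: float
    coverage_by_margin: dict = field(default_factory=dict)

    def metrics_dict(self) -> dict:
        return {
            "fet1_ml": self.fet1_ml,
            "mri1_ml": self.mri1_ml,
            "fet2_ml": self.fet2_ml,
            "mri2_ml": self.mri2_ml,
            "overlap1_fraction_of_fet1": self.overlap1_fraction_of_fet1,
            "overlap2_fraction_of_fet2": self.overlap2_fraction_of_fet2,
            "fet2_fraction_in_fet1": self.fet2_fraction_in_fet1,
            "cavity_shift_mm": self.cavity_shift_mm,
            "cavity_shrinkage_ml": self.cavity_shrinkage_ml,
        }


def _ball_mask(grid: GridSpec, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    coords = [
        np.arange(n) * s + o
        for n, s, o in zip(grid.shape, grid.spacing, grid.origin)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    d2 = (
        (xx - center_mm[0]) ** 2
        + (yy - center_mm[1]) ** 2
        + (zz - center_mm[2]) ** 2
    )
    return d2 <= radius_mm**2


def _require_inside_brain(
    name: str, center: np.ndarray, radius: float,
    brain_center: np.ndarray, brain_radius: float,
) -> None:
    if np.linalg.norm(center - brain_center) + radius > brain_radius:
        raise PhantomConfigurationError(
            f"{name} sphere (centre offset "
            f"{np.linalg.norm(center - brain_center):.1f} mm, radius {radius:.1f} mm) "
            f"does not fit inside the brain of radius {brain_radius:.1f} mm"
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place_sphere(
    anchor: np.ndarray,
    distance: float,
    radius: float,
    brain_center: np.ndarray,
    brain_radius: float,
    preferred_dirs: list[np.ndarray],
) -> np.ndarray:
    """Centre of a sphere at *distance* from *anchor* that fits inside the brain.

    Tries the preferred directions in order; if none fits, falls back to the
    direction pointing from the anchor back toward the brain centre, which
    minimises the centre's distance from the brain centre.
    """
    candidates = [_unit(d) for d in preferred_dirs]
    inward = brain_center - anchor
    if np.linalg.norm(inward) > 1e-9:
        candidates.append(_unit(inward))
    for direction in candidates:
        center = anchor + distance * direction
        if np.linalg.norm(center - brain_center) + radius <= brain_radius:
            return center
    raise PhantomConfigurationError(
        f"no placement at distance {distance:.1f} mm keeps a sphere of radius "
        f"{radius:.1f} mm inside the brain"
    )


def generate_case(
    config: PhantomConfig, case_id: str = "phantom-01"
) -> tuple[PatientCase, GroundTruth]:
    """Build one paired baseline/relapse phantom case plus its ground truth.

    The PET baseline is 1.0 inside the brain, 0 inside the cavity and
    ``fet1_tbr_level`` inside the baseline lesion (optionally plus additive
    Gaussian noise); the relapse PET is analogous with the shrunken,
    shifted cavity and the relapse lesion.  The MRI maps carry binary
    enhancement blobs at value 1.0.  A background reference mask is placed
    in the contralateral hemisphere.  Two calls with the same config are
    bitwise identical.
    """
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    brain_center = np.asarray(grid.origin) + (extent - np.asarray(grid.spacing)) / 2.0
    if config.brain_radius_mm * 2 > extent.min():
        raise PhantomConfigurationError(
            f"brain of radius {config.brain_radius_mm} mm does not fit the "
            f"{extent} mm grid"
        )

    # --- cavity: baseline in the "operated" hemisphere, relapse shrunk+shifted
    cavity1_center = brain_center + np.array([-18.0, 0.0, 0.0])
    r_cav1 = config.cavity_radius_baseline_mm
    r_cav2 = sphere_radius_for_volume_ml(
        sphere_volume_ml(r_cav1) - config.cavity_shrink_ml
    )
    shift_dir = _unit(np.array([0.55, 0.6, 0.58]) + rng.normal(0, 0.15, size=3))
    cavity2_center = cavity1_center + config.cavity_shift_mm * shift_dir

    # --- baseline lesion straddling the cavity rim
    fet1_dir = _unit(np.array([0.6, 0.8, 0.0]))
    fet1_dist = r_cav1 + config.fet1_rim_offset_mm
    fet1_center = cavity1_center + fet1_dist * fet1_dir
    # part of the lesion ball falls into the cavity; overlap targets are
    # expressed against the remaining (effective) lesion volume
    eff_fet1_ml = sphere_volume_ml(config.fet1_radius_mm) - lens_volume_ml(
        config.fet1_radius_mm, r_cav1, fet1_dist
    )

    # --- baseline MRI enhancement: offset solved for the target lens overlap
    d_mri1 = offset_for_overlap(
        config.fet1_radius_mm,
        config.mri1_radius_mm,
        config.mri1_overlap_fraction_of_fet1 * eff_fet1_ml,
    )
    mri1_center = _place_sphere(
        fet1_center,
        d_mri1,
        config.mri1_radius_mm,
        brain_center,
        config.brain_radius_mm,
        [fet1_center - cavity1_center, np.array([0.0, 0.2, 0.98])],
    )

    # --- relapse lesion: offset solved so the target fraction lies inside
    # FET-1; the effective relapse-lesion volume (after the relapse cavity
    # bite) depends on the placement, so the analytic solve is run through a
    # short fixed-point loop on the offset
    fet2_dirs = [np.array([0.35, 0.78, 0.35]), np.array([0.35, -0.78, 0.35])]
    eff_fet2_ml = sphere_volume_ml(config.fet2_radius_mm)
    d_fet2 = offset_for_overlap(
        config.fet1_radius_mm,
        config.fet2_radius_mm,
        config.fet2_fraction_in_fet1 * eff_fet2_ml,
    )
    for _ in range(3):
        fet2_center = _place_sphere(
            fet1_center,
            d_fet2,
            config.fet2_radius_mm,
            brain_center,
            config.brain_radius_mm,
            fet2_dirs,
        )
        eff_fet2_ml = sphere_volume_ml(config.fet2_radius_mm) - lens_volume_ml(
            config.fet2_radius_mm,
            r_cav2,
            float(np.linalg.norm(fet2_center - cavity2_center)),
        )
        d_fet2 = offset_for_overlap(
            config.fet1_radius_mm,
            config.fet2_radius_mm,
            config.fet2_fraction_in_fet1 * eff_fet2_ml,
        )
    fet2_center = _place_sphere(
        fet1_center, d_fet2, config.fet2_radius_mm,
        brain_center, config.brain_radius_mm, fet2_dirs,
    )

    d_mri2 = offset_for_overlap(
        config.fet2_radius_mm,
        config.mri2_radius_mm,
        config.mri2_overlap_fraction_of_fet2 * eff_fet2_ml,
    )
    mri2_center = _place_sphere(
        fet2_center,
        d_mri2,
        config.mri2_radius_mm,
        brain_center,
        config.brain_radius_mm,
        [np.array([-0.55, -0.2, 0.81]), np.array([-0.1, 0.6, 0.79])],
    )

    background_center = brain_center + np.array([32.0, -14.0, 0.0])

    for name, center, radius in (
        ("baseline cavity", cavity1_center, r_cav1),
        ("relapse cavity", cavity2_center, r_cav2),
        ("baseline FET lesion", fet1_center, config.fet1_radius_mm),
        ("baseline MRI enhancement", mri1_center, config.mri1_radius_mm),
        ("relapse FET lesion", fet2_center, config.fet2_radius_mm),
        ("relapse MRI enhancement", mri2_center, config.mri2_radius_mm),
        ("background reference", background_center, config.background_radius_mm),
    ):
        _require_inside_brain(
            name, center, radius, brain_center, config.brain_radius_mm
        )

    brain = _ball_mask(grid, brain_center, config.brain_radius_mm)
    cavity1 = _ball_mask(grid, cavity1_center, r_cav1)
    cavity2 = _ball_mask(grid, cavity2_center, r_cav2)
    fet1 = _ball_mask(grid, fet1_center, config.fet1_radius_mm) & brain & ~cavity1
    mri1 = _ball_mask(grid, mri1_center, config.mri1_radius_mm) & brain & ~cavity1
    fet2 = _ball_mask(grid, fet2_center, config.fet2_radius_mm) & brain & ~cavity2
    mri2 = _ball_mask(grid, mri2_center, config.mri2_radius_mm) & brain & ~cavity2
    background = _ball_mask(grid, background_center, config.background_radius_mm)

    def pet_image(cavity: np.ndarray, lesion: np.ndarray) -> np.ndarray:
        img = np.where(brain, 1.0, 0.0)
        img[cavity] = 0.0
        img[lesion] = config.fet1_tbr_level
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape) * brain
            img = np.clip(img, 0.0, None)
        return img

    def mri_image(blob: np.ndarray) -> np.ndarray:
        return np.where(blob, 1.0, 0.0)

    case = PatientCase(
        case_id=case_id,
        pet_baseline=ScalarVolume(grid, pet_image(cavity1, fet1)),
        pet_relapse=ScalarVolume(grid, pet_image(cavity2, fet2)),
        mri_baseline=ScalarVolume(grid, mri_image(mri1)),
        mri_relapse=ScalarVolume(grid, mri_image(mri2)),
        background_mask=BinaryMask(grid, background),
        cavity_baseline=BinaryMask(grid, cavity1),
        cavity_relapse=BinaryMask(grid, cavity2),
        brain_mask=BinaryMask(grid, brain),
        metadata={"config_seed": config.seed},
    )

    fet1_m, mri1_m = BinaryMask(grid, fet1), BinaryMask(grid, mri1)
    fet2_m, mri2_m = BinaryMask(grid, fet2), BinaryMask(grid, mri2)
    cav1_m, cav2_m = case.cavity_baseline, case.cavity_relapse
    _, ov1 = intersection_stats(fet1_m, mri1_m)
    _, ov2 = intersection_stats(fet2_m, mri2_m)
    _, in_fet1 = intersection_stats(fet2_m, fet1_m)
    truth = GroundTruth(
        fet1=fet1_m,
        mri1=mri1_m,
        fet2=fet2_m,
        mri2=mri2_m,
        cavity_baseline=cav1_m,
        cavity_relapse=cav2_m,
        fet1_ml=fet1_m.volume_ml,
        mri1_ml=mri1_m.volume_ml,
        fet2_ml=fet2_m.volume_ml,
        mri2_ml=mri2_m.volume_ml,
        overlap1_fraction_of_fet1=ov1,
        overlap2_fraction_of_fet2=ov2,
        fet2_fraction_in_fet1=in_fet1,
        cavity_shift_mm=cavity_shift(cav1_m, cav2_m),
        cavity_shrinkage_ml=cavity_shrinkage(cav1_m, cav2_m),
    )
    return case, truth


def generate_cohort(
    base_config: PhantomConfig, n_cases: int, seed: int | None = None
) -> list[tuple[PatientCase, GroundTruth]]:
    """Generate *n_cases* phantoms with per-case parameters jittered uniformly.

    Jitter (uniform, centred on the base configuration): cavity shift
    ±4 mm, cavity shrink ±6 ml, lesion/enhancement radii ±15 %, overlap
    fractions ±0.08 — so cohort means converge to the configured targets as
    the cohort grows.  A fixed seed reproduces the cohort bitwise;
    ``n_cases=1`` with no jitter draw differences still routes through the
    same per-case generator.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be at least 1")
    if seed is None:
        seed = base_config.seed
    rng = np.random.default_rng(seed)
    cohort: list[tuple[PatientCase, GroundTruth]] = []
    for i in range(n_cases):
        cfg = replace(
            base_config,
            cavity_shift_mm=max(
                0.0, base_config.cavity_shift_mm + rng.uniform(-4.0, 4.0)
            ),
            cavity_shrink_ml=max(
                1.0, base_config.cavity_shrink_ml + rng.uniform(-6.0, 6.0)
            ),
            fet1_radius_mm=base_config.fet1_radius_mm * rng.uniform(0.85, 1.15),
            mri1_radius_mm=base_config.mri1_radius_mm * rng.uniform(0.85, 1.15),
            fet2_radius_mm=base_config.fet2_radius_mm * rng.uniform(0.85, 1.15),
            mri2_radius_mm=base_config.mri2_radius_mm * rng.uniform(0.85, 1.15),
            mri1_overlap_fraction_of_fet1=float(
                np.clip(
                    base_config.mri1_overlap_fraction_of_fet1
                    + rng.uniform(-0.08, 0.08),
                    0.0,
                    1.0,
                )
            ),
            fet2_fraction_in_fet1=float(
                np.clip(
                    base_config.fet2_fraction_in_fet1 + rng.uniform(-0.08, 0.08),
                    0.0,
                    1.0,
                )
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(generate_case(cfg, case_id=f"phantom-{i + 1:02d}"))
    return cohort


def write_case(
    case: PatientCase, truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write a phantom case as NIfTI volumes/masks plus a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.pet_baseline, out / "pet_baseline.nii.gz")
    write_volume(case.pet_relapse, out / "pet_relapse.nii.gz")
    write_volume(case.mri_baseline, out / "mri_baseline.nii.gz")
    write_volume(case.mri_relapse, out / "mri_relapse.nii.gz")
    write_mask(case.background_mask, out / "background_mask.nii.gz")
    write_mask(case.cavity_baseline, out / "cavity_baseline.nii.gz")
    write_mask(case.cavity_relapse, out / "cavity_relapse.nii.gz")
    write_mask(case.brain_mask, out / "brain_mask.nii.gz")
    for name, mask in (
        ("fet1", truth.fet1),
        ("mri1", truth.mri1),
        ("fet2", truth.fet2),
        ("mri2", truth.mri2),
    ):
        write_mask(mask, out / f"truth_{name}.nii.gz")
    (out / "ground_truth.json").write_text(
        json.dumps(truth.metrics_dict(), indent=2) + "\n"
    )
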