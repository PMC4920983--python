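import math

import numpy as np
import pytest
from scipy import ndimage

from fetrelapse import (
    BinaryMask,
    EmptyStructureError,
    GridSpec,
    UndefinedFractionError,
    build_ctv,
    build_ptv,
    cavity_shift,
    cavity_shrinkage,
    centroid,
    coverage_fraction,
    expand_margin,
    intersection_stats,
    volume_ml,
)
from fetrelapse.phantom import sphere_volume_ml

from .conftest import make_sphere_mask


def ball_dilation_oracle(mask: BinaryMask, margin_mm: float) -> np.ndarray:
    """Brute-force dilation with an explicit anisotropic ball footprint."""
    spacing = np.asarray(mask.grid.spacing)
    reach = [int(math.floor(margin_mm / s + 1e-9)) for s in spacing]
    offsets = np.mgrid[
        -reach[0] : reach[0] + 1,
        -reach[1] : reach[1] + 1,
        -reach[2] : reach[2] + 1,
    ].astype(float)
    dist = np.sqrt(
        (offsets[0] * spacing[0]) ** 2
        + (offsets[1] * spacing[1]) ** 2
        + (offsets[2] * spacing[2]) ** 2
    )
    footprint = dist <= margin_mm * (1 + 1e-12) + 1e-9
    return ndimage.binary_dilation(mask.data, structure=footprint)


def shell_tolerance_ml(radius_mm: float, grid: GridSpec) -> float:
    """Volume of one voxel-shell on a sphere's surface."""
    h = np.linalg.norm(grid.spacing)  # voxel diagonal
    return 4 * math.pi * radius_mm**2 * h / 1000.0


# ---------------------------------------------------------------------- volume


def test_volume_ml_counts_voxels(unit_grid):
    data = np.zeros(unit_grid.shape, dtype=bool)
    assert volume_ml(BinaryMask(unit_grid, data)) == 0.0
    data.flat[:1000] = True
    assert volume_ml(BinaryMask(unit_grid, data)) == pytest.approx(1.0)
    grid2 = GridSpec(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0))
    data2 = np.zeros(grid2.shape, dtype=bool)
    data2.flat[:125] = True
    assert volume_ml(BinaryMask(grid2, data2)) == pytest.approx(1.0)


# ------------------------------------------------------------------- expansion


def test_zero_margin_is_identity(unit_grid):
    mask = make_sphere_mask(unit_grid, (16, 16, 16), 5.0)
    out = expand_margin(mask, 0.0)
    np.testing.assert_array_equal(out.data, mask.data)


def test_empty_mask_expansion_is_an_error(unit_grid):
    empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, dtype=bool))
    with pytest.raises(EmptyStructureError):
        expand_margin(empty, 5.0)


def test_single_voxel_expansion_is_digital_ball(unit_grid):
    data = np.zeros(unit_grid.shape, dtype=bool)
    data[16, 16, 16] = True
    mask = BinaryMask(unit_grid, data)
    out = expand_margin(mask, 5.0)
    np.testing.assert_array_equal(out.data, ball_dilation_oracle(mask, 5.0))


@pytest.mark.parametrize(
    "spacing", [(1.0, 1.0, 1.0), (2.0, 2.0, 2.0), (1.0, 1.0, 2.5), (0.9, 1.3, 2.1)]
)
@pytest.mark.parametrize("margin", [2.0, 5.0, 7.0])
def test_expansion_matches_bruteforce_oracle_random_masks(spacing, margin):
    grid = GridSpec(shape=(24, 24, 24), spacing=spacing)
    rng = np.random.default_rng(hash((spacing, margin)) % 2**31)
    for _ in range(5):
        data = rng.random(grid.shape) > 0.97
        if not data.any():
            data[12, 12, 12] = True
        mask = BinaryMask(grid, data)
        np.testing.assert_array_equal(
            expand_margin(mask, margin).data,
            ball_dilation_oracle(mask, margin),
        )


def test_margin_ladder_is_nested(unit_grid):
    mask = make_sphere_mask(unit_grid, (16, 16, 16), 4.0)
    m5 = expand_margin(mask, 5.0).data
    m7 = expand_margin(mask, 7.0).data
    m10 = expand_margin(mask, 10.0).data
    assert np.all(~m5 | m7) and np.all(~m7 | m10)
    assert np.all(~mask.data | m5)


def test_expansion_composition_within_one_voxel_shell():
    grid = GridSpec(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0))
    sphere = make_sphere_mask(grid, (24, 24, 24), 8.0)
    direct = expand_margin(sphere, 7.0)
    composed = expand_margin(expand_margin(sphere, 3.0), 4.0)
    assert direct.volume_ml >= composed.volume_ml
    assert abs(direct.volume_ml - composed.volume_ml) < shell_tolerance_ml(15.0, grid)


# ------------------------------------------------------------------- CTV / PTV


def test_ctv_margin_zero_equals_source(unit_grid):
    src = make_sphere_mask(unit_grid, (16, 16, 16), 5.0)
    ctv = build_ctv(src, 0.0)
    np.testing.assert_array_equal(ctv.mask.data, src.data)


def test_ctv_sphere_expansion_matches_analytic_volume():
    grid = GridSpec(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0))
    src = make_sphere_mask(grid, (24, 24, 24), 10.0)
    ctv = build_ctv(src, 7.0)
    assert abs(ctv.volume_ml - sphere_volume_ml(17.0)) < shell_tolerance_ml(17.0, grid)


def test_ctv_respects_brain_clip(unit_grid):
    src = make_sphere_mask(unit_grid, (16, 16, 16), 5.0)
    half = np.zeros(unit_grid.shape, dtype=bool)
    half[:16, :, :] = True
    brain = BinaryMask(unit_grid, half)
    ctv = build_ctv(src, 7.0, brain)
    assert not (ctv.mask.data & ~brain.data).any()


def test_ptv_setup_margin_zero_reproduces_ctv(unit_grid):
    ctv = build_ctv(make_sphere_mask(unit_grid, (16, 16, 16), 5.0), 0.0)
    ptv = build_ptv(ctv, setup_margin_mm=0.0)
    np.testing.assert_array_equal(ptv.mask.data, ctv.mask.data)
    assert ptv.label == "PTV"


def test_ptv_adds_setup_margin_around_ctv():
    grid = GridSpec(shape=(56, 56, 56), spacing=(1.0, 1.0, 1.0))
    ctv = build_ctv(make_sphere_mask(grid, (28, 28, 28), 10.0), 7.0)
    ptv = build_ptv(ctv, setup_margin_mm=5.0)
    assert np.all(~ctv.mask.data | ptv.mask.data)  # PTV superset of CTV
    assert abs(ptv.volume_ml - sphere_volume_ml(22.0)) < shell_tolerance_ml(22.0, grid)


# -------------------------------------------------------------------- overlaps


def test_intersection_stats_disjoint_and_contained(unit_grid):
    a = make_sphere_mask(unit_grid, (8, 8, 8), 4.0)
    b = make_sphere_mask(unit_grid, (24, 24, 24), 4.0)
    assert intersection_stats(a, b) == (0.0, 0.0)
    inside = make_sphere_mask(unit_grid, (8, 8, 8), 2.0)
    _, frac = intersection_stats(inside, a)
    assert frac == 1.0


def test_intersection_fraction_by_construction(unit_grid):
    data_a = np.zeros(unit_grid.shape, dtype=bool)
    data_a[:4, :4, :4] = True  # 64 voxels
    data_b = np.zeros(unit_grid.shape, dtype=bool)
    data_b[:2, :2, :4] = True  # 16 of them -> 25 %
    ml, frac = intersection_stats(
        BinaryMask(unit_grid, data_a), BinaryMask(unit_grid, data_b)
    )
    assert frac == pytest.approx(0.25)
    assert ml == pytest.approx(16 / 1000.0)


def test_empty_denominator_raises(unit_grid):
    empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, dtype=bool))
    full = make_sphere_mask(unit_grid, (16, 16, 16), 5.0)
    with pytest.raises(UndefinedFractionError):
        intersection_stats(empty, full)
    with pytest.raises(UndefinedFractionError):
        coverage_fraction(empty, build_ctv(full, 0.0))


def test_coverage_fraction_constructed_half(unit_grid):
    rec = np.zeros(unit_grid.shape, dtype=bool)
    rec[:4, :4, :4] = True
    target_data = np.zeros(unit_grid.shape, dtype=bool)
    target_data[:4, :4, :2] = True
    recurrence = BinaryMask(unit_grid, rec)
    target = build_ctv(BinaryMask(unit_grid, target_data), 0.0)
    assert coverage_fraction(recurrence, target) == pytest.approx(0.5)
    assert coverage_fraction(BinaryMask(unit_grid, target_data), target) == 1.0


def test_fractions_invariant_under_grid_translation():
    g1 = GridSpec(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0))
    g2 = GridSpec(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0), origin=(-40, 13, 7))
    rng = np.random.default_rng(9)
    a = rng.random(g1.shape) > 0.8
    b = rng.random(g1.shape) > 0.8
    _, f1 = intersection_stats(BinaryMask(g1, a), BinaryMask(g1, b))
    _, f2 = intersection_stats(BinaryMask(g2, a), BinaryMask(g2, b))
    assert f1 == f2


# ------------------------------------------------------------ cavity dynamics


def test_identical_cavities_have_no_dynamics(unit_grid):
    c = make_sphere_mask(unit_grid, (16, 16, 16), 6.0)
    assert cavity_shift(c, c) == 0.0
    assert cavity_shrinkage(c, c) == 0.0


def test_translated_mask_shift_is_exact_345(unit_grid):
    c1 = make_sphere_mask(unit_grid, (12, 12, 16), 5.0)
    c2_data = np.roll(np.roll(c1.data, 3, axis=0), 4, axis=1)
    c2 = BinaryMask(unit_grid, c2_data)
    assert cavity_shift(c1, c2) == pytest.approx(5.0)


def test_concentric_shrinking_spheres():
    grid = GridSpec(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0))
    c1 = make_sphere_mask(grid, (24, 24, 24), 20.0)
    c2 = make_sphere_mask(grid, (24, 24, 24), 15.0)
    assert cavity_shift(c1, c2) < 0.1
    analytic = sphere_volume_ml(20.0) - sphere_volume_ml(15.0)
    tol = shell_tolerance_ml(20.0, grid) + shell_tolerance_ml(15.0, grid)
    assert abs(cavity_shrinkage(c1, c2) - analytic) < tol


def test_centroid_of_empty_mask_is_error(unit_grid):
    empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, dtype=bool))
    with pytest.raises(EmptyStructureError):
        centroid(empty)
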