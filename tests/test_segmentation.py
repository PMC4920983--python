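import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetrelapse import (
    BinaryMask,
    ReferenceRegionError,
    ScalarVolume,
    autocontour_tbr,
    compute_tbr,
    enhancement_mask,
)
from fetrelapse.phantom import sphere_volume_ml

from .conftest import make_sphere_mask, make_uniform_volume


def background(grid, corner=4):
    data = np.zeros(grid.shape, dtype=bool)
    data[:corner, :corner, :corner] = True
    return BinaryMask(grid, data)


def test_uniform_pet_gives_unit_tbr(unit_grid):
    pet = make_uniform_volume(unit_grid, 7.3)
    tbr = compute_tbr(pet, background(unit_grid))
    np.testing.assert_allclose(tbr.tbr, 1.0)


def test_tbr_is_uptake_over_background_mean(unit_grid):
    values = np.full(unit_grid.shape, 2.0)
    values[10:14, 10:14, 10:14] = 3.2
    pet = ScalarVolume(unit_grid, values)
    tbr = compute_tbr(pet, background(unit_grid))
    assert tbr.background_reference == pytest.approx(2.0)
    assert tbr.tbr[12, 12, 12] == pytest.approx(1.6)


def test_zero_background_mean_is_reference_error(unit_grid):
    pet = make_uniform_volume(unit_grid, 0.0)
    with pytest.raises(ReferenceRegionError):
        compute_tbr(pet, background(unit_grid))


def test_empty_background_is_reference_error(unit_grid):
    pet = make_uniform_volume(unit_grid, 1.0)
    empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, dtype=bool))
    with pytest.raises(ReferenceRegionError):
        compute_tbr(pet, empty)


def test_threshold_is_inclusive_at_exact_equality(unit_grid):
    values = np.full(unit_grid.shape, 1.0)
    values[5, 5, 5] = 1.6  # exactly at the cut-off
    pet = ScalarVolume(unit_grid, values)
    mask = autocontour_tbr(compute_tbr(pet, background(unit_grid)), 1.6)
    assert mask.data[5, 5, 5]
    strict = autocontour_tbr(
        compute_tbr(pet, background(unit_grid)), 1.6, inclusive=False
    )
    assert not strict.data[5, 5, 5]


def test_subthreshold_image_gives_empty_contour(unit_grid):
    pet = make_uniform_volume(unit_grid, 1.0)
    mask = autocontour_tbr(compute_tbr(pet, background(unit_grid)), 1.6)
    assert mask.is_empty


def test_autocontour_monotone_in_threshold(unit_grid):
    rng = np.random.default_rng(3)
    pet = ScalarVolume(unit_grid, rng.uniform(0.5, 3.0, size=unit_grid.shape))
    tbr = compute_tbr(pet, background(unit_grid))
    lo = autocontour_tbr(tbr, 1.2)
    hi = autocontour_tbr(tbr, 1.8)
    assert np.all(~hi.data | lo.data)  # hi subset of lo


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_contour_invariant_under_global_rescaling(scale):
    grid_shape = (16, 16, 16)
    rng = np.random.default_rng(5)
    base = rng.uniform(0.5, 3.0, size=grid_shape)
    from fetrelapse import GridSpec

    grid = GridSpec(shape=grid_shape, spacing=(1.0, 1.0, 1.0))
    bg = background(grid)
    m1 = autocontour_tbr(compute_tbr(ScalarVolume(grid, base), bg), 1.6)
    m2 = autocontour_tbr(compute_tbr(ScalarVolume(grid, base * scale), bg), 1.6)
    np.testing.assert_array_equal(m1.data, m2.data)


def test_autocontoured_sphere_volume_near_analytic():
    # a 10 mm-radius hot sphere at TBR 2.0 on a 1 mm grid
    from fetrelapse import GridSpec

    grid = GridSpec(shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0))
    sphere = make_sphere_mask(grid, (20, 20, 20), 10.0)
    values = np.where(sphere.data, 2.0, 1.0)
    values[:4, :4, :4] = 1.0
    pet = ScalarVolume(grid, values)
    mask = autocontour_tbr(compute_tbr(pet, background(grid)), 1.6)
    analytic = sphere_volume_ml(10.0)
    shell = 4 * np.pi * 10.0**2 * np.sqrt(3) / 2 / 1000.0  # one voxel-shell
    assert abs(mask.volume_ml - analytic) < shell


def test_enhancement_mask_thresholds(unit_grid):
    zeros = make_uniform_volume(unit_grid, 0.0)
    assert enhancement_mask(zeros, 0.5).is_empty
    blob = np.zeros(unit_grid.shape)
    blob[2:6, 2:6, 2:6] = 1.0
    mask = enhancement_mask(ScalarVolume(unit_grid, blob), 0.5)
    assert mask.voxel_count == 4**3
    full = enhancement_mask(zeros, -1.0)  # threshold below global minimum
    assert full.voxel_count == np.prod(unit_grid.shape)
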