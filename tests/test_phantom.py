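import numpy as np
import pytest

from fetrelapse import (
    PhantomConfig,
    PhantomConfigurationError,
    PipelineConfig,
    autocontour_tbr,
    compute_tbr,
    generate_case,
    generate_cohort,
    segment_case,
)
from fetrelapse.phantom import (
    lens_volume_ml,
    offset_for_overlap,
    sphere_radius_for_volume_ml,
    sphere_volume_ml,
)


def test_lens_volume_limits():
    # tangent spheres share nothing; concentric smaller sphere is swallowed
    assert lens_volume_ml(10, 8, 18.0) == 0.0
    assert lens_volume_ml(10, 8, 1.0) == pytest.approx(sphere_volume_ml(8))
    # half-overlap sanity: symmetric spheres at distance r have lens
    # V = (4/3)pi r^3 * (1 - 3/4*(d/r)/2 + (d/r)^3/16) evaluated analytically
    r, d = 10.0, 10.0
    expected = np.pi * (2 * r - d) ** 2 * (d**2 + 4 * d * r) / (12 * d) / 1000.0
    assert lens_volume_ml(r, r, d) == pytest.approx(expected)


def test_offset_solver_inverts_lens_volume():
    for frac in (0.05, 0.12, 0.39, 0.8):
        target = frac * sphere_volume_ml(12.0)
        d = offset_for_overlap(14.0, 12.0, target)
        assert lens_volume_ml(14.0, 12.0, d) == pytest.approx(target, rel=1e-6)


def test_sphere_radius_volume_roundtrip():
    assert sphere_radius_for_volume_ml(sphere_volume_ml(17.3)) == pytest.approx(17.3)


def test_same_seed_is_bitwise_reproducible():
    cfg = PhantomConfig(noise_sd=0.05, seed=42)
    case_a, truth_a = generate_case(cfg)
    case_b, truth_b = generate_case(cfg)
    np.testing.assert_array_equal(
        case_a.pet_baseline.values, case_b.pet_baseline.values
    )
    np.testing.assert_array_equal(truth_a.fet2.data, truth_b.fet2.data)
    case_c, _ = generate_case(PhantomConfig(noise_sd=0.05, seed=43))
    assert not np.array_equal(case_a.pet_baseline.values, case_c.pet_baseline.values)


def test_noise_free_autocontour_recovers_truth_exactly(phantom_case):
    case, truth = phantom_case
    fet1 = autocontour_tbr(
        compute_tbr(case.pet_baseline, case.background_mask), 1.6
    )
    np.testing.assert_array_equal(fet1.data, truth.fet1.data)
    fet2 = autocontour_tbr(
        compute_tbr(case.pet_relapse, case.background_mask), 1.6
    )
    np.testing.assert_array_equal(fet2.data, truth.fet2.data)


def test_small_noise_only_perturbs_threshold_shell():
    cfg = PhantomConfig(noise_sd=0.02, seed=5)
    case, truth = generate_case(cfg)
    seg = segment_case(case, PipelineConfig())
    # voxels that flipped relative to truth must touch the lesion boundary
    diff = seg.fet1.data ^ truth.fet1.data
    from scipy import ndimage

    boundary_zone = ndimage.binary_dilation(
        truth.fet1.data, iterations=1
    ) & ~ndimage.binary_erosion(truth.fet1.data, iterations=1)
    assert not (diff & ~boundary_zone).any()


def test_ground_truth_metrics_recomputable_from_masks(phantom_case):
    _, truth = phantom_case
    inter = truth.fet1.intersect(truth.mri1)
    assert truth.overlap1_fraction_of_fet1 == pytest.approx(
        inter.volume_ml / truth.fet1.volume_ml
    )
    assert truth.cavity_shrinkage_ml == pytest.approx(
        truth.cavity_baseline.volume_ml - truth.cavity_relapse.volume_ml
    )


def test_achieved_fractions_near_configured_targets(phantom_case):
    _, truth = phantom_case
    cfg = PhantomConfig()
    assert truth.overlap1_fraction_of_fet1 == pytest.approx(
        cfg.mri1_overlap_fraction_of_fet1, abs=0.03
    )
    assert truth.fet2_fraction_in_fet1 == pytest.approx(
        cfg.fet2_fraction_in_fet1, abs=0.03
    )
    assert truth.cavity_shift_mm == pytest.approx(cfg.cavity_shift_mm, abs=0.5)
    assert truth.cavity_shrinkage_ml == pytest.approx(cfg.cavity_shrink_ml, abs=1.5)


def test_cohort_mean_shift_within_sampling_tolerance(phantom_cohort):
    shifts = [t.cavity_shift_mm for _, t in phantom_cohort]
    # uniform +-4 mm jitter around 6 mm: 3 standard errors of the mean
    se = 4.0 / np.sqrt(3.0) / np.sqrt(len(shifts))
    assert abs(np.mean(shifts) - 6.0) < 3 * se + 0.3  # + voxelization slack


def test_cohort_is_reproducible_and_case_ids_unique(phantom_cohort):
    again = generate_cohort(PhantomConfig(), 13, seed=11)
    ids = [c.case_id for c, _ in phantom_cohort]
    assert len(set(ids)) == 13
    np.testing.assert_array_equal(
        phantom_cohort[4][0].pet_relapse.values, again[4][0].pet_relapse.values
    )


def test_single_case_cohort_equals_generate_case():
    cohort = generate_cohort(PhantomConfig(seed=3), 1, seed=3)
    assert len(cohort) == 1


def test_oversized_geometry_is_rejected():
    with pytest.raises(PhantomConfigurationError):
        generate_case(PhantomConfig(brain_radius_mm=200.0))
    with pytest.raises(PhantomConfigurationError):
        PhantomConfig(cavity_shrink_ml=1e4)
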