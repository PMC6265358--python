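import numpy as np
import pytest

from y90pet.core_io import EmptyInputError, Mask, boundary_voxels, volume_cm3
from y90pet.segmentation import (DegenerateInputError, GradientInit,
                                 GradientParams, gradient_segment,
                                 init_from_mask, optimal_threshold,
                                 threshold_bound_from_mask, threshold_segment)
from y90pet.synthetic import (PET_SPACING, LesionSpec, NoiseSpec, PhantomSpec,
                              build_truth, ellipsoid_mask, sphere_radius_mm)


def _pet_grid_image(values=None, shape=(41, 41, 41)):
    from y90pet.core_io import VoxelImage

    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, PET_SPACING))
    if values is None:
        values = np.zeros(shape)
    return VoxelImage(values=values, spacing=PET_SPACING, origin=origin)


class TestInitFromMask:
    def test_centered_sphere_rays_near_radius(self):
        grid = _pet_grid_image()
        mask = ellipsoid_mask(grid, (0, 0, 0), (24.0, 24.0, 24.0))
        init = init_from_mask(mask)
        assert np.allclose(init.seed_mm, (0, 0, 0), atol=2.1)
        for ray, sp in zip(init.ray_lengths, (4.07, 4.07, 4.07, 4.07, 3.0, 3.0)):
            assert abs(ray - 24.0) <= 0.51 * sp + 1e-9

    def test_ellipsoid_rays_match_semi_axes(self):
        grid = _pet_grid_image()
        mask = ellipsoid_mask(grid, (0, 0, 0), (30.0, 20.0, 15.0))
        init = init_from_mask(mask)
        expected = (30.0, 30.0, 20.0, 20.0, 15.0, 15.0)
        for ray, exp, sp in zip(init.ray_lengths, expected,
                                (4.07, 4.07, 4.07, 4.07, 3.0, 3.0)):
            assert abs(ray - exp) <= 0.51 * sp + 1e-9

    def test_hollow_rim_seed_relocated_into_mask(self):
        grid = _pet_grid_image()
        shell = ellipsoid_mask(grid, (0, 0, 0), (24.0, 24.0, 24.0)).values \
            & ~ellipsoid_mask(grid, (0, 0, 0), (14.0, 14.0, 14.0)).values
        mask = Mask(values=shell, grid=grid)
        init = init_from_mask(mask)
        seed_idx = np.round((np.asarray(init.seed_mm) - np.asarray(grid.origin))
                            / np.asarray(grid.spacing)).astype(int)
        assert mask.values[tuple(seed_idx)]

    def test_empty_mask_raises(self):
        grid = _pet_grid_image()
        with pytest.raises(EmptyInputError):
            init_from_mask(Mask(values=np.zeros(grid.shape, dtype=bool), grid=grid))


class TestGradientSegment:
    def test_sharp_sphere_recovered_within_voxel_shell(self):
        grid = _pet_grid_image()
        truth = ellipsoid_mask(grid, (0, 0, 0), (24.0, 24.0, 24.0))
        img = grid.with_values(np.where(truth.values, 10.0, 0.0))
        ps = gradient_segment(img, init_from_mask(truth))
        shell = boundary_voxels(truth).n_voxels * grid.voxel_volume_cm3
        assert abs(volume_cm3(ps) - volume_cm3(truth)) <= shell
        assert np.count_nonzero(ps.values & truth.values) / truth.n_voxels > 0.9

    def test_blurred_warm_sphere_radius_within_1mm(self, noiseless_suite):
        # the directional-gradient maximum sits at the edge inflection, which
        # for a blurred step profile is the true sphere radius
        case = noiseless_suite[1]  # 60 cm³ warm TBR 5
        ps = gradient_segment(case.pet, init_from_mask(case.truth_masks[0]))
        r_rec = sphere_radius_mm(volume_cm3(ps))
        assert abs(r_rec - sphere_radius_mm(60.0)) < 1.0

    def test_scale_invariance(self, noiseless_suite):
        case = noiseless_suite[1]
        init = init_from_mask(case.truth_masks[0])
        a = gradient_segment(case.pet, init)
        b = gradient_segment(case.pet.with_values(case.pet.values * 37.5), init)
        np.testing.assert_array_equal(a.values, b.values)

    def test_connected_and_contains_seed(self, phantom_report):
        from scipy import ndimage

        from y90pet import PipelineConfig, make_phantom_suite, run_case

        case = make_phantom_suite(seed=1)[2]
        for r in run_case(case, PipelineConfig(), seed=13):
            labels, n = ndimage.label(r.ps1_mask.values,
                                      structure=np.ones((3, 3, 3), dtype=int))
            assert n == 1

    def test_deterministic(self, noiseless_suite):
        case = noiseless_suite[2]
        init = init_from_mask(case.truth_masks[0])
        params = GradientParams(jitter_sigma=2.0)
        a = gradient_segment(case.pet, init, params, seed=5)
        b = gradient_segment(case.pet, init, params, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_flat_image_degenerate(self):
        grid = _pet_grid_image(np.full((41, 41, 41), 7.0))
        init = GradientInit(seed_mm=(0, 0, 0), ray_lengths=(20,) * 6)
        with pytest.raises(DegenerateInputError):
            gradient_segment(grid, init)

    def test_seed_outside_grid_rejected(self, noiseless_suite):
        case = noiseless_suite[0]
        init = GradientInit(seed_mm=(500.0, 0, 0), ray_lengths=(20,) * 6)
        with pytest.raises(ValueError):
            gradient_segment(case.pet, init)


class TestBoundingEllipsoid:
    def test_octant_radius_on_axes_equals_signed_ray(self):
        init = GradientInit(seed_mm=(0, 0, 0),
                            ray_lengths=(10, 20, 30, 40, 50, 60), margin=1.0)
        axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        assert np.allclose(init.bound_radius(axes), [10, 20, 30, 40, 50, 60])

    def test_margin_scales_bound(self):
        init = GradientInit(seed_mm=(0, 0, 0), ray_lengths=(10,) * 6, margin=1.3)
        d = np.array([[0.6, 0.64, 0.48]])
        assert init.bound_radius(d)[0] == pytest.approx(13.0)


class TestThresholdSegment:
    def test_binary_object_recovered_at_any_pct(self):
        grid = _pet_grid_image()
        truth = ellipsoid_mask(grid, (0, 0, 0), (20.0, 20.0, 20.0))
        img = grid.with_values(np.where(truth.values, 4.0, 0.0))
        bound = threshold_bound_from_mask(truth)
        for pct in (10.0, 50.0, 90.0):
            np.testing.assert_array_equal(
                threshold_segment(img, bound, pct).values, truth.values)

    def test_pct_near_100_single_voxel(self):
        grid = _pet_grid_image()
        rng = np.random.default_rng(1)
        img = grid.with_values(rng.random(grid.shape))
        bound = Mask(values=np.ones(grid.shape, dtype=bool), grid=grid)
        assert threshold_segment(img, bound, 99.99).n_voxels == 1

    def test_scale_invariant(self, noiseless_suite):
        case = noiseless_suite[1]
        bound = threshold_bound_from_mask(case.truth_masks[0])
        a = threshold_segment(case.pet, bound, 40.0)
        b = threshold_segment(case.pet.with_values(case.pet.values * 11.0), bound, 40.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_bound_rejected(self):
        grid = _pet_grid_image()
        with pytest.raises(EmptyInputError):
            threshold_segment(grid, Mask(values=np.zeros(grid.shape, dtype=bool),
                                         grid=grid), 50.0)


class TestOptimalThreshold:
    def test_binary_object_tie_breaks_low(self):
        grid = _pet_grid_image()
        truth = ellipsoid_mask(grid, (0, 0, 0), (20.0, 20.0, 20.0))
        img = grid.with_values(np.where(truth.values, 4.0, 0.0))
        pct = optimal_threshold(img, threshold_bound_from_mask(truth),
                                volume_cm3(truth))
        assert pct == 1.0  # every pct is exact; ties break toward the lowest

    def test_warm_optimum_exceeds_cold_optimum(self, noiseless_suite):
        cold, warm = noiseless_suite[0], noiseless_suite[1]
        target = volume_cm3(cold.truth_masks[0])
        p_cold = optimal_threshold(cold.pet,
                                   threshold_bound_from_mask(cold.truth_masks[0]), target)
        p_warm = optimal_threshold(warm.pet,
                                   threshold_bound_from_mask(warm.truth_masks[0]), target)
        assert p_warm > p_cold

    def test_cold_optimum_overestimates_in_warm_background(self, noiseless_suite):
        cold, warm = noiseless_suite[0], noiseless_suite[1]
        target = volume_cm3(cold.truth_masks[0])
        p_cold = optimal_threshold(cold.pet,
                                   threshold_bound_from_mask(cold.truth_masks[0]), target)
        v = volume_cm3(threshold_segment(
            warm.pet, threshold_bound_from_mask(warm.truth_masks[0]), p_cold))
        assert v > target
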