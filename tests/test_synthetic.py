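import numpy as np
import pytest

from y90pet.core_io import GeometryError
from y90pet.synthetic import (LesionSpec, NoiseSpec, PhantomSpec, add_noise,
                              apply_psf, build_truth, make_patient_cohort,
                              make_phantom_suite, sphere_radius_mm)


class TestBuildTruth:
    def test_uniform_liver_concentration(self):
        # 3.0 GBq spread over the bare liver: concentration = activity / volume
        spec = PhantomSpec(lesions=(), total_activity_gbq=3.0)
        activity, masks, liver = build_truth(spec)
        conc = activity.values[liver.values]
        assert np.all(conc == conc[0])
        liver_ml = liver.n_voxels * activity.voxel_volume_cm3
        assert conc[0] == pytest.approx(3.0e9 / liver_ml, rel=1e-9)
        # liver volume ≈ 1200 cm³ → ≈ 2.5 MBq/mL
        assert conc[0] == pytest.approx(2.5e6, rel=0.01)

    def test_tbr_exact_before_blur(self):
        spec = PhantomSpec(lesions=(LesionSpec.sphere((0, 0, 0), 60.0, tbr=5.0),))
        activity, (lesion,), liver = build_truth(spec)
        bg = liver.values & ~lesion.values
        ratio = activity.values[lesion.values].mean() / activity.values[bg].mean()
        assert ratio == pytest.approx(5.0, rel=1e-12)

    def test_total_activity_conserved(self):
        spec = PhantomSpec(lesions=(
            LesionSpec.sphere((-45, 0, 0), 8.0, tbr=5.1),
            LesionSpec.sphere((0, 0, 0), 16.0, tbr=6.2)))
        activity, _, _ = build_truth(spec)
        total = activity.values.sum() * activity.voxel_volume_cm3
        assert total == pytest.approx(3.0e9, rel=1e-3)

    def test_cold_background_sphere(self):
        spec = PhantomSpec(lesions=(LesionSpec.sphere((0, 0, 0), 60.0, tbr=5.0),),
                           total_activity_gbq=0.625, cold_background=True)
        activity, (lesion,), _ = build_truth(spec)
        assert not np.any(activity.values[~lesion.values])
        # rasterized mask volume within one voxel shell of the nominal 60 cm³
        vol = lesion.n_voxels * activity.voxel_volume_cm3
        assert abs(vol - 60.0) < 4 * np.pi * sphere_radius_mm(60.0) ** 2 * 4.07 / 1000

    def test_necrotic_core_is_cold(self):
        spec = PhantomSpec(lesions=(
            LesionSpec.sphere((0, 0, 0), 60.0, tbr=5.0, core_fraction=0.5),))
        activity, (lesion,), _ = build_truth(spec)
        center = tuple(np.array(activity.shape) // 2)
        assert activity.values[center] == 0.0
        assert activity.values[lesion.values].max() > 0

    def test_overlapping_lesions_rejected(self):
        spec = PhantomSpec(lesions=(
            LesionSpec.sphere((0, 0, 0), 16.0, tbr=5.0),
            LesionSpec.sphere((5, 0, 0), 16.0, tbr=5.0)))
        with pytest.raises(GeometryError):
            build_truth(spec)

    def test_lesion_outside_liver_rejected(self):
        spec = PhantomSpec(lesions=(LesionSpec.sphere((200, 0, 0), 8.0, tbr=5.0),))
        with pytest.raises(GeometryError):
            build_truth(spec)


class TestPsf:
    def test_zero_fwhm_is_identity(self, make_image):
        img = make_image(shape=(8, 8, 8), value=2.0)
        np.testing.assert_array_equal(apply_psf(img, 0.0).values, img.values)

    def test_negative_fwhm_rejected(self, make_image):
        with pytest.raises(ValueError):
            apply_psf(make_image(), -1.0)

    def test_total_preserved(self):
        spec = PhantomSpec(lesions=(LesionSpec.sphere((0, 0, 0), 60.0, tbr=5.0),))
        activity, _, _ = build_truth(spec)
        blurred = apply_psf(activity, 5.0)
        assert blurred.values.sum() == pytest.approx(activity.values.sum(), rel=1e-3)

    def test_delta_spreads_to_stated_fwhm(self, make_image):
        img = make_image(shape=(41, 41, 41), spacing=(1.0, 1.0, 1.0))
        values = img.values.copy()
        values[20, 20, 20] = 1.0
        blurred = apply_psf(img.with_values(values), 5.0)
        for axis in range(3):
            profile = blurred.values.sum(axis=tuple(a for a in range(3) if a != axis))
            x = np.arange(41) - 20
            var = (profile * x ** 2).sum() / profile.sum() - 1.0 / 12.0
            fwhm = 2.3548 * np.sqrt(var)
            assert fwhm == pytest.approx(5.0, rel=0.02)

    def test_uniform_interior_unchanged(self, make_image):
        img = make_image(shape=(31, 31, 31), value=3.0)
        blurred = apply_psf(img, 5.0)
        assert blurred.values[10:21, 10:21, 10:21] == pytest.approx(3.0, rel=1e-6)

    def test_contrast_reduced_below_tbr_after_blur(self, noiseless_suite):
        case = noiseless_suite[2]  # 8/16/29 cm³ lesion set
        bg = case.liver_mask.values.copy()
        for m in case.truth_masks:
            bg &= ~m.values
        bg_mean = case.pet.values[bg].mean()
        for les, mask in zip(case.spec.lesions, case.truth_masks):
            contrast = case.pet.values[mask.values].mean() / bg_mean
            assert contrast < les.tbr


class TestNoise:
    def test_zero_cov_is_identity(self, make_image):
        img = make_image(value=1.0)
        out = add_noise(img, NoiseSpec(background_cov=0.0), seed=1)
        np.testing.assert_array_equal(out.values, img.values)

    def test_deterministic_given_seed(self, make_image):
        img = make_image(shape=(16, 16, 16), value=1.0)
        a = add_noise(img, NoiseSpec(), seed=11)
        b = add_noise(img, NoiseSpec(), seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        c = add_noise(img, NoiseSpec(), seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_realized_cov_matches_target(self, make_image):
        img = make_image(shape=(48, 48, 48), value=1.0)
        out = add_noise(img, NoiseSpec(background_cov=0.25), seed=2,
                        reference_level=1.0)
        interior = out.values[4:-4, 4:-4, 4:-4]
        cov = interior.std() / interior.mean()
        assert cov == pytest.approx(0.25, abs=0.025)

    def test_cov_monotone_in_target(self, make_image):
        img = make_image(shape=(32, 32, 32), value=1.0)
        covs = []
        for target in (0.1, 0.25, 0.4):
            out = add_noise(img, NoiseSpec(background_cov=target), seed=3,
                            reference_level=1.0)
            inner = out.values[3:-3, 3:-3, 3:-3]
            covs.append(inner.std() / inner.mean())
        assert covs[0] < covs[1] < covs[2]

    def test_never_negative(self, make_image):
        img = make_image(shape=(24, 24, 24), value=0.05)
        out = add_noise(img, NoiseSpec(background_cov=0.8), seed=4,
                        reference_level=0.05)
        assert np.all(out.values >= 0)


class TestPhantomSuite:
    def test_three_cases_with_expected_lesions(self):
        suite = make_phantom_suite(seed=0)
        assert [len(c.truth_masks) for c in suite] == [1, 1, 3]

    def test_lesion_set_tbrs(self):
        suite = make_phantom_suite(seed=0)
        assert [l.tbr for l in suite[2].spec.lesions] == [5.1, 6.2, 5.5]
        activity = suite[2].truth_activity
        bg = suite[2].liver_mask.values.copy()
        for m in suite[2].truth_masks:
            bg &= ~m.values
        c_b = activity.values[bg].mean()
        for les, mask in zip(suite[2].spec.lesions, suite[2].truth_masks):
            assert activity.values[mask.values].max() / c_b == pytest.approx(les.tbr)

    def test_reproducible_given_seed(self):
        a = make_phantom_suite(seed=5)
        b = make_phantom_suite(seed=5)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.pet.values, cb.pet.values)


class TestPatientCohort:
    def test_volumes_within_stated_range(self):
        cases = make_patient_cohort(n_patients=4, seed=9)
        for case in cases:
            for les in case.spec.lesions:
                assert 2.0 <= les.target_volume_cm3 <= 818.0

    def test_perfect_registration_reproduces_truth_masks(self):
        cases = make_patient_cohort(n_patients=2, seed=9, registration_sigma_mm=0.0)
        for case in cases:
            for tm, ms in zip(case.truth_masks, case.ms_masks):
                np.testing.assert_array_equal(tm.values, ms.values)

    def test_deterministic_given_seed(self):
        a = make_patient_cohort(n_patients=2, seed=21)
        b = make_patient_cohort(n_patients=2, seed=21)
        assert [c.lesion_ids for c in a] == [c.lesion_ids for c in b]
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.pet.values, cb.pet.values)
            for ma, mb in zip(ca.ms_masks, cb.ms_masks):
                np.testing.assert_array_equal(ma.values, mb.values)

    def test_patient_identity_recorded(self):
        cases = make_patient_cohort(n_patients=3, seed=1)
        assert [c.patient_id for c in cases] == ["p00", "p01", "p02"]
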