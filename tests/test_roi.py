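"""ROI machinery: mirroring, rater intersection, hemispheres, the
difference-map thresholding pipeline, tensor fitting, FA, and the
voxelwise FA group comparison."""

import numpy as np
import pytest

from neurofp.errors import DegenerateRoiError, ValidationError
from neurofp.io import RoiMask
from neurofp.phantom import (
    LesionSpec,
    PhantomParams,
    make_subject,
    make_tensor_field,
    simulate_signal,
)
from neurofp.preprocess import gaussian_smooth, mean_over_gradients
from neurofp.roi import (
    ThresholdPair,
    derive_thresholds,
    difference_map,
    fa_map,
    fit_tensor,
    hemisphere_mask,
    intersect_rater_masks,
    mirror_mask,
    pooled_roi_differences,
    segment_auto_voxelwise,
    segment_semiauto,
)


def _mask(shape, voxels):
    data = np.zeros(shape, bool)
    for v in voxels:
        data[v] = True
    return RoiMask(data)


class TestMirrorAndHemispheres:
    def test_mirror_is_an_involution_preserving_count(self):
        rng = np.random.default_rng(0)
        m = RoiMask(rng.random((9, 7, 5)) < 0.3)
        mm = mirror_mask(mirror_mask(m))
        assert np.array_equal(mm.data, m.data)
        assert mirror_mask(m).n_voxels == m.n_voxels

    def test_single_voxel_reflection_coordinates(self):
        m = _mask((48, 8, 6), [(3, 5, 2)])
        assert mirror_mask(m).data[44, 5, 2]
        assert mirror_mask(m).n_voxels == 1

    def test_midplane_symmetric_mask_is_fixed_point(self):
        data = np.zeros((10, 6, 4), bool)
        data[2] = data[7] = True
        m = RoiMask(data)
        assert np.array_equal(mirror_mask(m).data, m.data)

    def test_hemispheres_partition_symmetric_brain(self, noiseless_symmetric):
        brain = noiseless_symmetric.brain_mask
        left = hemisphere_mask(brain, "left")
        right = hemisphere_mask(brain, "right")
        assert left.n_voxels == right.n_voxels
        assert not (left.data & right.data).any()
        assert np.array_equal(mirror_mask(left).data, right.data)

    def test_odd_width_midplane_column_in_neither_hemisphere(self):
        brain = RoiMask(np.ones((9, 4, 4)))
        left = hemisphere_mask(brain, "left")
        right = hemisphere_mask(brain, "right")
        assert not left.data[4].any()
        assert not right.data[4].any()
        assert left.n_voxels == right.n_voxels == 4 * 4 * 4

    def test_hemisphere_target_never_meets_its_mirror(self, noiseless_symmetric):
        left = hemisphere_mask(noiseless_symmetric.brain_mask, "left")
        assert not (left.data & mirror_mask(left).data).any()


class TestRaterIntersection:
    def test_identical_masks_pass_through(self):
        m = _mask((8, 8, 4), [(1, 1, 1), (2, 2, 2)])
        assert np.array_equal(intersect_rater_masks(m, m).data, m.data)

    def test_partial_overlap_counts(self):
        a = _mask((8, 8, 4), [(i, 0, 0) for i in range(8)] + [(0, 1, 0), (0, 2, 0)])
        b = _mask((8, 8, 4), [(i, 0, 0) for i in range(2, 8)] + [(0, 3, 0), (0, 4, 0)])
        assert intersect_rater_masks(a, b).n_voxels == 6

    def test_disjoint_masks_raise(self):
        a = _mask((8, 8, 4), [(0, 0, 0)])
        b = _mask((8, 8, 4), [(7, 7, 3)])
        with pytest.raises(DegenerateRoiError):
            intersect_rater_masks(a, b)


class TestDifferenceMap:
    def test_symmetric_image_gives_zero_map(self, noiseless_symmetric):
        img = mean_over_gradients(noiseless_symmetric.dwi)
        diff = difference_map(img, noiseless_symmetric.brain_mask)
        assert np.allclose(diff, 0.0, atol=1e-9)

    def test_antisymmetry(self, cohort19):
        s = cohort19[8]  # an acute subject
        img = mean_over_gradients(s.dwi)
        diff = difference_map(img, s.brain_mask)
        flipped = -diff[::-1]
        inner = s.brain_mask.data & s.brain_mask.data[::-1]
        assert np.allclose(diff[inner], flipped[inner], atol=1e-9)

    def test_single_voxel_arithmetic(self):
        img = np.zeros((4, 3, 3))
        img[0, 1, 1] = 120.0
        img[3, 1, 1] = 100.0
        diff = difference_map(img, RoiMask(np.ones((4, 3, 3))))
        assert diff[0, 1, 1] == 20.0
        assert diff[3, 1, 1] == -20.0


class TestThresholds:
    def test_pair_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ThresholdPair(5.0, -5.0)

    def test_equal_variance_gaussians_cross_at_midpoint(self):
        """Two equal-variance Gaussian densities cross exactly halfway
        between their means; KDE should land within +-1 of that."""
        rng = np.random.default_rng(42)
        seq = rng.normal(-10.0, 2.0, 4000)
        normal = rng.normal(0.0, 2.0, 4000)
        acute = rng.normal(10.0, 2.0, 4000)
        t = derive_thresholds(normal, acute, seq)
        assert t.t1 == pytest.approx(-5.0, abs=1.0)
        assert t.t2 == pytest.approx(5.0, abs=1.0)

    def test_identical_distributions_trigger_fallback_warning(self):
        rng = np.random.default_rng(1)
        same = rng.normal(0.0, 1.0, 500)
        with pytest.warns(UserWarning):
            t = derive_thresholds(same, same, same)
        assert t.t1 < t.t2

    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError):
            derive_thresholds(np.array([0.0]), np.ones(10), -np.ones(10))

    def test_phantom_references_give_bracketing_thresholds(self, cohort19):
        t = _phantom_thresholds(cohort19)
        assert t.t1 < 0 < t.t2


def _phantom_thresholds(cohort):
    refs = {}
    for s in cohort:
        refs.setdefault(s.clinical_class, s)
    pooled = {}
    for cls, s in refs.items():
        img = mean_over_gradients(gaussian_smooth(s.dwi, 3.0))
        target = (s.truth_lesion if not s.truth_lesion.is_empty
                  else hemisphere_mask(s.brain_mask, "left"))
        pooled[cls] = pooled_roi_differences(img, s.brain_mask, target)
    return derive_thresholds(pooled[1], pooled[2], pooled[3])


class TestSemiautoSegmentation:
    def test_acute_phantom_dice_at_least_half(self, cohort19):
        thresholds = _phantom_thresholds(cohort19)
        acute = next(s for s in cohort19 if s.clinical_class == 2)
        img = mean_over_gradients(gaussian_smooth(acute.dwi, 3.0))
        roi, kind = segment_semiauto(img, acute.brain_mask, thresholds)
        assert kind == "acute"
        inter = (roi.data & acute.truth_lesion.data).sum()
        dice = 2 * inter / (roi.n_voxels + acute.truth_lesion.n_voxels)
        assert dice >= 0.5

    def test_noiseless_normal_yields_no_lesion(self, noiseless_symmetric):
        img = mean_over_gradients(noiseless_symmetric.dwi)
        roi, kind = segment_semiauto(img, noiseless_symmetric.brain_mask,
                                     ThresholdPair(-5.0, 5.0))
        assert kind == "no-lesion"
        assert roi.is_empty

    def test_infinite_thresholds_select_nothing(self, cohort19):
        s = cohort19[0]
        img = mean_over_gradients(s.dwi)
        big = float(np.abs(img).max() * 10 + 1)
        roi, kind = segment_semiauto(img, s.brain_mask, ThresholdPair(-big, big))
        assert kind == "no-lesion"
        assert roi.is_empty

    def test_output_within_brain_and_one_hemisphere(self, cohort19):
        thresholds = _phantom_thresholds(cohort19)
        for s in cohort19:
            img = mean_over_gradients(gaussian_smooth(s.dwi, 3.0))
            roi, kind = segment_semiauto(img, s.brain_mask, thresholds)
            if roi.is_empty:
                continue
            assert np.all(s.brain_mask.data[roi.data])
            xs = np.flatnonzero(roi.data.any(axis=(1, 2)))
            nx = roi.data.shape[0]
            assert (xs < nx / 2).all() or (xs >= nx / 2).all()


class TestTensorFit:
    def test_noiseless_parameter_recovery(self, noiseless_acute):
        fitted = fit_tensor(noiseless_acute.dwi, noiseless_acute.brain_mask)
        truth = noiseless_acute.tensor_field
        err = np.abs(fitted.components - truth.components)
        assert err[noiseless_acute.brain_mask.data].max() < 1e-6

    def test_isotropic_voxel_trace_recovery(self, scheme):
        from neurofp.phantom import TensorField
        comps = np.zeros((16, 16, 8, 6))
        comps[..., :3] = 0.8e-3
        img = simulate_signal(TensorField(comps, (1, 1, 5)), 100.0, scheme)
        brain = RoiMask(np.ones((16, 16, 8)))
        # signal model zeroes background only where the tensor is zero;
        # here every voxel is isotropic tissue
        fitted = fit_tensor(img, brain)
        md = fitted.mean_diffusivity()
        assert np.allclose(md, 0.8e-3, atol=1e-9)

    def test_too_few_directions_rejected(self):
        from neurofp.io import DwiImage, GradientScheme
        vecs = np.vstack([np.zeros(3), np.eye(3), [[0.6, 0.8, 0], [0, 0.6, 0.8]]])
        scheme5 = GradientScheme([0] + [1000] * 5, vecs)
        img = DwiImage(np.ones((16, 16, 8, 6)), (1, 1, 5), scheme5)
        with pytest.raises(ValidationError, match=">= 6"):
            fit_tensor(img, RoiMask(np.ones((16, 16, 8))))

    def test_nonpositive_signal_voxels_skipped(self, scheme):
        from neurofp.io import DwiImage
        data = np.ones((16, 16, 8, 21))
        data[..., 1:] = 0.5  # uniform attenuation -> nonzero tensors
        data[0, 0, 0, 3] = 0.0  # dead voxel
        img = DwiImage(data, (1, 1, 5), scheme)
        fitted = fit_tensor(img, RoiMask(np.ones((16, 16, 8))))
        assert np.all(fitted.components[0, 0, 0] == 0)
        assert np.any(fitted.components[1, 1, 1] != 0)


class TestFaMap:
    def _fa_of(self, eigenvalues):
        from neurofp.phantom import TensorField
        comps = np.zeros((1, 1, 1, 6))
        comps[0, 0, 0, :3] = eigenvalues
        return fa_map(TensorField(comps, (1, 1, 1)))[0, 0, 0]

    def test_isotropic_tensor_has_zero_fa(self):
        assert self._fa_of([1e-3, 1e-3, 1e-3]) == pytest.approx(0.0, abs=1e-12)

    def test_rank_one_tensor_has_unit_fa(self):
        assert self._fa_of([1e-3, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_prolate_tensor_matches_eigenvalue_formula(self):
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        expected = np.sqrt(1.5 * ((lam - lam.mean()) ** 2).sum() / (lam**2).sum())
        assert expected == pytest.approx(0.79902, abs=1e-4)
        assert self._fa_of(lam) == pytest.approx(expected, abs=1e-12)

    def test_background_fa_is_zero(self, noiseless_symmetric):
        fa = fa_map(noiseless_symmetric.tensor_field)
        assert np.all(fa[~noiseless_symmetric.brain_mask.data] == 0)
        brain_fa = fa[noiseless_symmetric.brain_mask.data]
        assert np.all((brain_fa >= 0) & (brain_fa <= 1))
        assert np.allclose(brain_fa, 0.30, atol=1e-9)


def _fa_cohort(n, seed0, params, cls=1):
    maps = []
    for i in range(n):
        s = make_subject(i, cls, params, seed=seed0 + i)
        maps.append(fa_map(fit_tensor(s.dwi, s.brain_mask)))
    return maps


class TestAutoVoxelwise:
    def test_null_false_positive_rate_near_alpha(self, small_params):
        """Patients and controls drawn from the same phantom distribution:
        the fraction of tested voxels below alpha should match alpha
        within a 3-sigma binomial band."""
        alpha = 0.005
        pat = _fa_cohort(8, 100, small_params)
        ctl = _fa_cohort(8, 200, small_params)
        roi = segment_auto_voxelwise(pat, ctl, alpha=alpha)
        tested = (np.stack(pat).var(axis=0) > 0) | (np.stack(ctl).var(axis=0) > 0)
        n = int(tested.sum())
        fp = roi.n_voxels
        sd = np.sqrt(n * alpha * (1 - alpha))
        assert abs(fp - n * alpha) < 3 * sd

    def test_strong_fa_drop_detected(self, small_params):
        """An fa_scale=0.3 lesion shared across patients should be caught
        in >= 80% of its voxels at alpha=0.005 with 8 vs 8 subjects."""
        import dataclasses
        from neurofp.phantom import add_rician_noise
        lesion_params = dataclasses.replace(small_params, lesion_fa_scale=0.3,
                                            acute_adc_scale=0.999999)
        # identical lesion geometry across patients (one noiseless
        # template), independent Rician noise per patient
        tpl = make_subject(0, 2, lesion_params, seed=300, noiseless=True)
        truth = tpl.truth_lesion
        sigma = lesion_params.noise_sigma_frac * lesion_params.s0
        patients = []
        for i in range(8):
            noisy = add_rician_noise(tpl.dwi, sigma, seed=300 + i)
            patients.append(fa_map(fit_tensor(noisy, tpl.brain_mask)))
        ctl = _fa_cohort(8, 400, small_params)
        roi = segment_auto_voxelwise(patients, ctl, alpha=0.005)
        detected = (roi.data & truth.data).sum() / truth.n_voxels
        assert detected >= 0.8

    def test_alpha_one_returns_all_tested_voxels(self, small_params):
        pat = _fa_cohort(2, 500, small_params)
        ctl = _fa_cohort(2, 600, small_params)
        roi = segment_auto_voxelwise(pat, ctl, alpha=1.0)
        tested = (np.stack(pat).var(axis=0) > 0) | (np.stack(ctl).var(axis=0) > 0)
        assert np.array_equal(roi.data, tested)

    def test_single_image_group_rejected(self, small_params):
        pat = _fa_cohort(2, 700, small_params)
        with pytest.raises(ValidationError):
            segment_auto_voxelwise(pat[:1], pat, alpha=0.005)
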