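import numpy as np
import pytest

from uterseg.core import BinaryMask, IntensityVolume, PipelineConfig
from uterseg.phantom import generate, known_misregistration, preset
from uterseg.refine import (
    AffineTransform,
    correlation_ratio,
    last_peak_threshold,
    mask_intensities,
    params_to_transform,
    postprocess,
    register_affine,
    resample,
    threshold_refine,
)

from .reference_impl import reference_valley_threshold


class TestAffineTransform:
    def test_identity_leaves_points_unchanged(self, rng):
        pts = rng.normal(size=(10, 3))
        assert np.allclose(AffineTransform.identity().apply(pts), pts)

    def test_inverse_composes_to_identity(self, rng):
        tr = params_to_transform(
            np.array([3, -2, 1, 5, -4, 8, 2, -1, 3, 1, 0.5, -0.5]), np.zeros(3)
        )
        both = tr.compose(tr.inverse())
        assert np.allclose(both.matrix, np.eye(3), atol=1e-12)
        assert np.allclose(both.translation, 0, atol=1e-10)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))


class TestResample:
    def _vol(self, data, spacing=(1, 1, 1)):
        return IntensityVolume(np.asarray(data, float), spacing)

    def test_identity_transform_is_voxel_exact(self, rng):
        vol = self._vol(rng.normal(size=(12, 10, 6)))
        out = resample(vol, AffineTransform.identity())
        assert np.allclose(out.data, vol.data, atol=1e-12)

    def test_integer_voxel_translation_is_exact_shift(self, rng):
        vol = self._vol(rng.normal(size=(12, 10, 6)))
        tr = AffineTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        out = resample(vol, tr)
        # out(i) = vol(i + 2) along x; border reads 0
        assert np.allclose(out.data[:-2], vol.data[2:], atol=1e-12)
        assert np.allclose(out.data[-2:], 0.0)

    def test_half_voxel_shift_averages_step_neighbours(self):
        data = np.zeros((10, 4, 4))
        data[5:] = 8.0  # step along x
        out = resample(self._vol(data), AffineTransform(np.eye(3), np.array([0.5, 0, 0])))
        # trilinear weights at half-voxel: midpoint of the two neighbours
        assert np.allclose(out.data[4, 1, 1], 4.0)
        assert np.allclose(out.data[3, 1, 1], 0.0)
        assert np.allclose(out.data[5, 1, 1], 8.0)

    def test_anisotropic_spacing_honoured(self, rng):
        vol = self._vol(rng.normal(size=(8, 8, 8)), spacing=(1, 1, 3))
        # 3 mm translation along z == exactly one slice
        tr = AffineTransform(np.eye(3), np.array([0.0, 0.0, 3.0]))
        out = resample(vol, tr)
        assert np.allclose(out.data[:, :, :-1], vol.data[:, :, 1:], atol=1e-12)


class TestResampleCrossCheck:
    def test_matches_simpleitk_affine_resampling(self, rng):
        """Independent oracle: SimpleITK's resampler with the same
        affine map, grid and linear interpolation."""
        sitk = pytest.importorskip("SimpleITK")
        data = rng.normal(size=(14, 12, 8))
        spacing = (0.78, 0.78, 7.0)
        vol = IntensityVolume(data, spacing)
        tr = params_to_transform(
            np.array([1.5, -2.0, 3.0, 0, 0, 4.0, 2.0, 0, 0, 0, 0, 0]), np.zeros(3)
        )
        ours = resample(vol, tr)

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))  # sitk is z,y,x
        img.SetSpacing(spacing)
        t = sitk.AffineTransform(3)
        t.SetMatrix(tr.matrix.ravel())
        t.SetTranslation(tr.translation)
        out = sitk.Resample(img, img, t, sitk.sitkLinear, 0.0)
        theirs = sitk.GetArrayFromImage(out).T

        # the two tools differ only in how they blend samples that fall
        # partially outside the grid; compare strictly interior samples
        idx = np.indices(data.shape, dtype=float)
        phys = idx * np.asarray(spacing)[:, None, None, None]
        src = np.einsum("ij,j...->i...", tr.matrix, phys) + tr.translation[:, None, None, None]
        src_vox = src / np.asarray(spacing)[:, None, None, None]
        interior = np.ones(data.shape, bool)
        for ax, n in enumerate(data.shape):
            interior &= (src_vox[ax] >= 1.0) & (src_vox[ax] <= n - 2.0)
        assert interior.sum() > 200
        assert np.allclose(ours.data[interior], theirs[interior], atol=1e-5)


class TestCorrelationRatio:
    def test_perfect_functional_dependence_scores_one(self, rng):
        x = rng.integers(0, 4, 4000).astype(float)
        y = x * 7.0 + 1.0
        assert correlation_ratio(x, y, bins=8) > 0.999

    def test_independent_images_score_near_zero(self, rng):
        x = rng.normal(size=20000)
        y = rng.normal(size=20000)
        assert correlation_ratio(x, y, bins=16) < 0.01

    def test_invariant_to_monotone_remap_of_moving_image(self, rng):
        moving = rng.uniform(0, 100, 5000)
        fixed = moving * 0.5 + rng.normal(0, 5, 5000)
        base = correlation_ratio(moving, fixed, bins=32)
        remapped = correlation_ratio(np.exp(moving / 25.0), fixed, bins=32)
        assert np.isclose(base, remapped, atol=1e-12)

    def test_constant_image_scores_zero(self):
        assert correlation_ratio(np.ones(100), np.arange(100.0)) == 0.0
        assert correlation_ratio(np.arange(100.0), np.ones(100)) == 0.0


class TestLastPeakThreshold:
    def test_bimodal_threshold_lies_between_modes(self, rng, config):
        values = np.concatenate(
            [rng.normal(80, 8, 12000), rng.normal(160, 8, 2500)]
        )
        hist = last_peak_threshold(values, config)
        assert not hist.single_peak_fallback
        assert 96 < hist.threshold < 144
        ref_thr, maxima = reference_valley_threshold(values, config.histogram_bins, config.histogram_smoothing)
        assert ref_thr is not None
        assert np.isclose(hist.threshold, ref_thr, atol=1e-9)

    def test_minority_bright_mode_still_detected(self, rng, config):
        values = np.concatenate([rng.normal(80, 6, 20000), rng.normal(170, 5, 900)])
        hist = last_peak_threshold(values, config)
        assert 92 < hist.threshold < 165

    def test_unimodal_threshold_above_max(self, rng, config):
        values = rng.normal(100, 10, 5000)
        hist = last_peak_threshold(values, config)
        assert hist.single_peak_fallback
        assert hist.threshold > values.max()

    def test_constant_input_falls_back(self, config):
        hist = last_peak_threshold(np.full(100, 7.0), config)
        assert hist.single_peak_fallback and hist.threshold > 7.0

    def test_empty_input_rejected(self, config):
        with pytest.raises(ValueError):
            last_peak_threshold(np.empty(0), config)

    def test_counts_sum_to_masked_voxels(self, rng, config):
        values = rng.normal(100, 10, 3456)
        hist = last_peak_threshold(values, config)
        assert hist.counts.sum() == 3456


class TestThresholdRefine:
    def _setup(self, rng):
        vol = IntensityVolume(rng.uniform(0, 100, (10, 10, 4)), (1, 1, 1))
        cand = BinaryMask(rng.random((10, 10, 4)) < 0.5, (1, 1, 1))
        return vol, cand

    def test_mask_intensities_cardinality(self, rng):
        vol, cand = self._setup(rng)
        vals = mask_intensities(vol, cand)
        assert len(vals) == cand.voxel_count
        assert np.allclose(np.sort(vals), np.sort(vol.data[cand.data]))

    def test_empty_candidate_warns_and_returns_empty(self, rng):
        vol, _ = self._setup(rng)
        empty = BinaryMask(np.zeros((10, 10, 4), bool), (1, 1, 1))
        with pytest.warns(UserWarning):
            assert mask_intensities(vol, empty).size == 0

    def test_threshold_above_all_keeps_candidate(self, rng, config):
        vol, cand = self._setup(rng)
        hist = last_peak_threshold(vol.data[cand.data], config)
        out = threshold_refine(cand, vol, _with_thr(hist, 1e9))
        assert np.array_equal(out.data, cand.data)

    def test_threshold_below_all_empties_with_warning(self, rng, config):
        vol, cand = self._setup(rng)
        hist = _with_thr(last_peak_threshold(vol.data[cand.data], config), -1.0)
        with pytest.warns(UserWarning):
            out = threshold_refine(cand, vol, hist)
        assert out.voxel_count == 0

    def test_output_is_subset_of_candidate(self, rng, config):
        vol, cand = self._setup(rng)
        hist = last_peak_threshold(vol.data[cand.data], config)
        out = threshold_refine(cand, vol, hist)
        assert np.all(out.data <= cand.data)


def _with_thr(hist, thr):
    import dataclasses

    return dataclasses.replace(hist, threshold=thr)


class TestPostprocess:
    def test_empty_mask_stays_empty(self, config):
        empty = BinaryMask(np.zeros((8, 8, 4), bool), (1, 1, 1))
        assert postprocess(empty, config).voxel_count == 0

    def test_large_smooth_region_essentially_unchanged(self, config):
        from .conftest import blob_mask

        m = blob_mask((40, 40, 20), (20, 20, 10), 12.0)
        out = postprocess(m, config)
        assert out.voxel_count > 0.97 * m.voxel_count

    def test_thin_tether_removed(self, config):
        data = np.zeros((40, 40, 8), bool)
        data[10:30, 10:30, 2:6] = True  # 1600-voxel block
        data[19:21, 30:39, 3] = True  # thin tether sticking out
        out = postprocess(BinaryMask(data, (1, 1, 1)), config)
        assert not out.data[19, 35, 3]
        assert out.data[20, 20, 3]


class TestRegistration:
    def test_self_registration_recovers_identity(self, small_spec):
        _, t1c, _ = generate(small_spec)
        cfg = PipelineConfig(registration_multistart=1)
        tr = register_affine(t1c, t1c, cfg)
        assert np.abs(tr.translation).max() < 0.1  # < 0.1 voxel at 1 mm
        assert np.abs(tr.matrix - np.eye(3)).max() < 0.01

    def test_known_translation_recovered(self, small_spec):
        import dataclasses

        shift = AffineTransform(np.eye(3), np.array([3.0, -2.0, 0.0]))
        spec = dataclasses.replace(small_spec, misregistration=shift)
        t1, t1c, _ = generate(spec)
        cfg = PipelineConfig(registration_multistart=1)
        tr = register_affine(t1, t1c, cfg)
        err_vox = (tr.translation - shift.translation) / np.array(spec.spacing)
        assert np.abs(err_vox).max() < 0.5

    def test_uninformative_content_returns_identity_with_warning(self):
        fixed = IntensityVolume(np.random.default_rng(0).normal(size=(16, 16, 4)), (1, 1, 1))
        moving = IntensityVolume(np.full((16, 16, 4), 3.0), (1, 1, 1))
        cfg = PipelineConfig(registration_multistart=1)
        with pytest.warns(UserWarning):
            tr = register_affine(moving, fixed, cfg)
        assert np.allclose(tr.matrix, np.eye(3)) and np.allclose(tr.translation, 0)
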