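import numpy as np
import pytest
from scipy import stats

from brainaccel.alff import (ALFFMap, VoxelTimeSeries, aggregate_regions,
                             bandpass_amplitude, compute_alff_map,
                             smooth_gaussian, subject_alff, threshold_clusters,
                             voxelwise_group_stats)
from brainaccel.effects import fit_effect
from brainaccel.synthetic import FmriSpec, generate_fmri

from conftest import make_subjects

N, TR = 500, 1.0  # 0.05 Hz and 0.2 Hz fall exactly on DFT bins
T = np.arange(N) * TR


def centered_cosine(freq, amplitude=1.0):
    """Whole-period cosine, even around the series midpoint, so the
    detrending line is exactly zero and bin leakage vanishes."""
    return amplitude * np.cos(2 * np.pi * freq * (T - (N - 1) / 2.0))


class TestBandpassAmplitude:
    def test_constant_series_zero(self):
        assert bandpass_amplitude(np.full(64, 3.7), TR) == pytest.approx(
            0.0, abs=1e-12)

    def test_amplitude_linearity(self):
        s = np.sin(2 * np.pi * 0.05 * T)
        a1 = bandpass_amplitude(s, TR)
        a2 = bandpass_amplitude(2.0 * s, TR)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)
        assert a1 > 0

    def test_out_of_band_rejection(self):
        in_band = bandpass_amplitude(centered_cosine(0.05), TR)
        out_band = bandpass_amplitude(centered_cosine(0.2), TR)
        assert out_band <= 1e-8 * in_band

    def test_trend_and_offset_invariance(self):
        s = np.sin(2 * np.pi * 0.04 * T)
        base = bandpass_amplitude(s, TR)
        shifted = bandpass_amplitude(s + 42.0 + 0.31 * T, TR)
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_amplitude(np.sin(T), TR, band=(0.01, 0.6))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bandpass_amplitude(np.ones(8), TR)


class TestComputeAlffMap:
    def _uniform_vol(self, value_scale=1.0):
        sig = value_scale * np.sin(2 * np.pi * 0.05 * T)
        data = np.broadcast_to(sig, (4, 4, 4, N)).copy()
        return VoxelTimeSeries(data=data, tr=TR, mask=np.ones((4, 4, 4), bool))

    def test_uniform_signal_normalizes_to_one(self):
        amap = compute_alff_map(self._uniform_vol())
        assert amap.values[amap.values == amap.values] == pytest.approx(1.0)
        assert np.nanmean(amap.values) == pytest.approx(1.0, abs=1e-6)

    def test_global_scale_invariance(self):
        a1 = compute_alff_map(self._uniform_vol(1.0))
        a2 = compute_alff_map(self._uniform_vol(7.3))
        np.testing.assert_allclose(a1.values, a2.values, rtol=1e-12)

    def test_out_of_mask_is_missing(self):
        vol = self._uniform_vol()
        vol.mask[0, 0, 0] = False
        amap = compute_alff_map(vol)
        assert np.isnan(amap.values[0, 0, 0])
        assert np.nanmean(amap.values[vol.mask]) == pytest.approx(1.0, abs=1e-6)

    def test_empty_mask_rejected(self):
        vol = self._uniform_vol()
        vol.mask[:] = False
        with pytest.raises(ValueError):
            compute_alff_map(vol)

    def test_planted_cluster_has_elevated_alff(self):
        vox = np.argwhere(np.zeros((8, 8, 8)) == 0)[:20]
        spec = FmriSpec(grid_shape=(8, 8, 8), n_timepoints=200, noise_sd=0.1,
                        cluster_definitions=[(vox, {1: 2.0})], seed=3)
        vols = generate_fmri(spec, [1])
        amap = compute_alff_map(vols[0])
        in_cluster = amap.values[tuple(vox.T)]
        assert in_cluster.mean() > 1.0


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 6, 6))
        np.testing.assert_array_equal(smooth_gaussian(v, 0.0), v)

    def test_uniform_field_unchanged(self):
        out = smooth_gaussian(np.full((12, 12, 12), 5.0), fwhm=5.0)
        np.testing.assert_allclose(out[3:-3, 3:-3, 3:-3], 5.0, rtol=1e-7)

    def test_delta_matches_closed_form_gaussian(self):
        v = np.zeros((21, 21, 21))
        v[10, 10, 10] = 1.0
        fwhm = 4.0
        out = smooth_gaussian(v, fwhm)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        g1 = stats.norm.pdf(np.arange(-10, 11), scale=sigma)
        g1 /= g1.sum()  # discrete kernel normalization
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        # scipy truncates the kernel at 4 sigma; tails are ~1e-6
        np.testing.assert_allclose(out, expected, atol=2e-5)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((4, 4, 4)), -1.0)


class TestVoxelwiseGroupStats:
    def test_matches_statsmodels_per_voxel(self):
        rng = np.random.default_rng(11)
        maps = [rng.normal(size=(3, 3, 2)) for _ in range(14)]
        factor = np.repeat([0.0, 1.0], 7)
        cov = rng.normal(size=14)
        z = voxelwise_group_stats(maps, factor, covariates=cov)
        cohort = make_subjects([{} for _ in range(14)])
        cohort["g"] = factor
        cohort["c"] = cov
        for idx in [(0, 0, 0), (2, 1, 1), (1, 2, 0)]:
            y = np.array([m[idx] for m in maps])
            est = fit_effect(y, cohort, "g", ["c"])
            p_two = est.p
            z_ref = np.sign(est.t) * stats.norm.isf(p_two / 2)
            assert z[idx] == pytest.approx(z_ref, rel=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(23)
        maps = [rng.normal(size=(12, 12, 12)) for _ in range(40)]
        z = voxelwise_group_stats(maps, np.repeat([0.0, 1.0], 20))
        frac = np.mean(np.abs(z) > 1.96)
        assert 0.035 <= frac <= 0.065

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_group_stats([np.zeros((2, 2, 2)), np.zeros((3, 2, 2))],
                                  np.array([0.0, 1.0]))

    def test_missing_voxel_propagates(self):
        rng = np.random.default_rng(5)
        maps = [rng.normal(size=(2, 2, 2)) for _ in range(10)]
        maps[3][0, 0, 0] = np.nan
        z = voxelwise_group_stats(maps, np.repeat([0.0, 1.0], 5))
        assert np.isnan(z[0, 0, 0]) and np.isfinite(z[1, 1, 1])


class TestThresholdClusters:
    def _zmap_with_blobs(self):
        rng = np.random.default_rng(77)
        z = rng.normal(size=(15, 15, 15)) * 0.5
        z[2:7, 2:6, 2] = 8.0    # 20-voxel slab
        z[10:11, 10:15, 10] = 8.0  # 5-voxel line
        return z

    def test_extent_threshold_keeps_only_large_blob(self):
        clusters = threshold_clusters(self._zmap_with_blobs(), q=0.05, min_size=12)
        assert len(clusters) == 1
        assert clusters.clusters[0].size == 20
        assert clusters.clusters[0].sign == 1

    def test_degenerate_thresholds_cover_everything(self):
        z = np.random.default_rng(1).normal(size=(6, 6, 6))
        clusters = threshold_clusters(z, q=1.0, min_size=1)
        total = sum(c.size for c in clusters.clusters)
        assert total == z.size

    def test_monotone_in_q(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(10, 10, 10)) * 1.5
        z[4:8, 4:8, 4:6] += 4.0
        vox_at = {}
        for q in (0.01, 0.05, 0.2):
            cl = threshold_clusters(z, q=q, min_size=1)
            vox_at[q] = {tuple(v) for c in cl.clusters for v in c.voxels}
        assert vox_at[0.01] <= vox_at[0.05] <= vox_at[0.2]

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            threshold_clusters(np.zeros((3, 3, 3)), q=0.0)

    def test_signs_never_mix(self):
        z = np.zeros((10, 4, 4))
        z[0:5] = 8.0
        z[5:10] = -8.0
        clusters = threshold_clusters(z, q=0.05, min_size=12)
        assert {c.sign for c in clusters.clusters} == {1, -1}
        assert all(c.size == 80 for c in clusters.clusters)


class TestAggregateRegions:
    def test_uniform_map(self):
        labels = np.ones((4, 4, 4), dtype=int)
        out = aggregate_regions(np.full((4, 4, 4), 3.3), labels)
        assert out[1] == pytest.approx(3.3)

    def test_two_planted_regions(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        vol = np.where(labels == 1, 1.0, 2.0)
        out = aggregate_regions(vol, labels, region_names={1: "a", 2: "b"})
        assert out["a"] == 1.0 and out["b"] == 2.0

    def test_nan_voxels_skipped_and_empty_region_warns(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0] = 1
        labels[1] = 2
        vol = np.full((3, 3, 3), np.nan)
        vol[0] = 4.0
        with pytest.warns(UserWarning, match="no usable voxels"):
            out = aggregate_regions(vol, labels)
        assert out[1] == 4.0 and np.isnan(out[2])


class TestSubjectAlff:
    def test_smooth_after_preserves_mask_and_mean_scale(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(10, 10, 10, 64))
        mask = np.ones((10, 10, 10), bool)
        mask[0] = False
        vol = VoxelTimeSeries(data=data, tr=1.0, mask=mask)
        amap = subject_alff(vol, fwhm=3.0, smooth_first=False)
        assert np.isnan(amap.values[0]).all()
        assert np.isfinite(amap.values[mask]).all()
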