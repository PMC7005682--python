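"""fALFF, map standardization, ROI identification and summaries."""

import numpy as np
import pytest

from ffapls.neuro import (
    VoxelMaps,
    compute_falff,
    identify_roi,
    split_half_measures,
    standardize_map,
    summarize_roi,
)
from ffapls.inference import icc
from ffapls.synthetic import CohortConfig, ROISpec, simulate_genotypes, simulate_phenotypes, simulate_voxel_maps


class TestFalff:
    def test_pure_in_band_sinusoid(self):
        t = np.arange(240) * 2.0
        ts = np.sin(2 * np.pi * 0.05 * t)
        assert compute_falff(ts, 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_matches_bandwidth_fraction(self):
        """Flat spectrum: expected fALFF is the in-band bin fraction."""
        rng = np.random.default_rng(0)
        n, tr = 240, 2.0
        freqs = np.fft.rfftfreq(n, d=tr)
        total = (freqs > 0) & (freqs <= 0.25)
        low = total & (freqs >= 0.01) & (freqs <= 0.08)
        expected = low.sum() / total.sum()
        vals = [compute_falff(rng.standard_normal(n), tr) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(expected, abs=0.02)

    def test_out_of_band_sinusoid_near_zero(self):
        t = np.arange(240) * 2.0
        ts = np.sin(2 * np.pi * 0.2 * t)
        assert compute_falff(ts, 2.0) < 0.05

    def test_constant_series_flagged_nan(self):
        assert np.isnan(compute_falff(np.ones(240), 2.0))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = compute_falff(rng.standard_normal(128), 2.0)
            assert 0.0 <= v <= 1.0

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            compute_falff(np.random.default_rng(2).standard_normal(128), 3.0)


class TestStandardizeMap:
    def test_exact_moments(self):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((10, 10, 10))
        mask = rng.random((10, 10, 10)) > 0.3
        out = standardize_map(m, mask)
        assert abs(out[mask].mean()) < 1e-12
        assert abs(out[mask].std() - 1) < 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=bool)
        np.testing.assert_allclose(standardize_map(3.2 * m - 7, mask),
                                   standardize_map(m, mask), atol=1e-10)

    def test_two_voxel_population_sd_convention(self):
        m = np.zeros((2, 1, 1))
        m[0, 0, 0], m[1, 0, 0] = 1.0, 3.0
        out = standardize_map(m, np.ones((2, 1, 1), dtype=bool))
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0])

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError, match="standard deviation"):
            standardize_map(np.ones((3, 3, 3)), np.ones((3, 3, 3), dtype=bool))


class TestIdentifyRoi:
    def test_all_subthreshold_empty(self):
        roi = identify_roi(np.zeros((5, 5, 5)), np.ones((5, 5, 5), bool), 2.58)
        assert len(roi.voxels) == 0 and roi.components == []

    def test_corner_touching_blobs_connectivity(self):
        z = np.zeros((4, 4, 4))
        z[1, 1, 1] = 3.0
        z[2, 2, 2] = 3.0
        mask = np.ones((4, 4, 4), bool)
        assert len(identify_roi(z, mask, 2.58, connectivity=26).components) == 1
        assert len(identify_roi(z, mask, 2.58, connectivity=6).components) == 2

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((8, 8, 8)) * 2
        mask = np.ones((8, 8, 8), bool)
        a = identify_roi(z, mask, 2.0)
        b = identify_roi(z.copy(order="F"), mask, 2.0)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert a.sizes == b.sizes

    def test_union_vs_largest(self):
        z = np.zeros((6, 6, 6))
        z[1:3, 1, 1] = 3.0
        z[4, 4, 4] = 3.0
        mask = np.ones((6, 6, 6), bool)
        largest = identify_roi(z, mask, 2.58, connectivity=6, roi="largest")
        union = identify_roi(z, mask, 2.58, connectivity=6, roi="union")
        assert len(largest.voxels) == 2 and len(union.voxels) == 3

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            identify_roi(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool), 0.0)


def _maps(values, mask=None, kind="contrast_z", voxel_size=(2.0, 2.0, 2.0)):
    data = np.asarray(values, dtype=float)
    mask = np.ones(data.shape[1:], bool) if mask is None else mask
    return VoxelMaps(subject_ids=[f"s{i}" for i in range(data.shape[0])],
                     kind=kind, data=data, mask=mask, voxel_size=voxel_size)


class TestSummarizeRoi:
    def test_constant_map_summary(self):
        shape = (2, 4, 4, 4)
        c = _maps(np.full(shape, 2.0))
        f = _maps(np.full(shape, 0.5), kind="falff")
        g = _maps(np.full(shape, 0.25), kind="gm_modulated")
        voxels = np.array([[1, 1, 1], [1, 1, 2], [2, 1, 1]])
        rec = summarize_roi(c, f, g, voxels, standardize_falff=False)
        np.testing.assert_allclose(rec.fs, 2.0)
        np.testing.assert_allclose(rec.falff, 0.5)
        np.testing.assert_allclose(rec.gmv, 0.25 * 3 * 8.0)

    def test_voxel_permutation_invariance_of_means(self):
        rng = np.random.default_rng(6)
        c = _maps(rng.standard_normal((3, 5, 5, 5)))
        f = _maps(rng.standard_normal((3, 5, 5, 5)), kind="falff")
        g = _maps(rng.random((3, 5, 5, 5)), kind="gm_modulated")
        voxels = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [1, 2, 3]])
        a = summarize_roi(c, f, g, voxels)
        b = summarize_roi(c, f, g, voxels[::-1])
        np.testing.assert_allclose(a.fs, b.fs, atol=1e-12)
        np.testing.assert_allclose(a.gmv, b.gmv, atol=1e-12)

    def test_gmv_residualized_orthogonal_to_tbv(self):
        rng = np.random.default_rng(7)
        g = _maps(rng.random((50, 5, 5, 5)) + 0.1, kind="gm_modulated")
        c = _maps(rng.standard_normal((50, 5, 5, 5)))
        f = _maps(rng.standard_normal((50, 5, 5, 5)), kind="falff")
        voxels = np.array([[1, 1, 1], [2, 2, 2]])
        tbv = rng.normal(1.2e6, 1e5, size=50)
        rec = summarize_roi(c, f, g, voxels, total_brain_volume=tbv)
        assert abs(np.corrcoef(rec.gmv_resid, tbv)[0, 1]) < 1e-10

    def test_roi_outside_mask_raises(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        c = _maps(np.zeros((2, 4, 4, 4)), mask=mask)
        f = _maps(np.zeros((2, 4, 4, 4)), mask=mask, kind="falff")
        g = _maps(np.zeros((2, 4, 4, 4)), mask=mask, kind="gm_modulated")
        with pytest.raises(ValueError, match="outside"):
            summarize_roi(c, f, g, np.array([[0, 0, 0]]))


class TestNiftiIO:
    def test_map_written_and_read_back(self, tmp_path):
        import nibabel as nib
        rng = np.random.default_rng(8)
        vm = _maps(rng.standard_normal((2, 6, 6, 6)), voxel_size=(2.0, 2.0, 3.0))
        path = tmp_path / "sub0.nii.gz"
        vm.to_nifti(path, subject_index=0)
        img = nib.load(str(path))
        np.testing.assert_allclose(img.get_fdata(), vm.data[0], atol=1e-6)
        np.testing.assert_allclose(img.header.get_zooms(), (2.0, 2.0, 3.0))


class TestSplitHalf:
    def _sim(self, noise, n=40, blob=60, seed=0):
        cfg = CohortConfig(n_subjects=n, seed=seed)
        table, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(table, cfg)
        spec = ROISpec(blob_size=blob)
        sim = simulate_voxel_maps(spec, pheno, cfg,
                                  rng=np.random.default_rng(seed + 100),
                                  voxel_noise_sd=noise)
        roi = identify_roi(sim.group_zmap, sim.hemi_masks["right"], 2.58)
        true_fs = (pheno[pheno.hemisphere == "right"]
                   .set_index("subject").loc[table.subject_ids, "fs"].to_numpy())
        return sim, roi, true_fs

    def test_fixed_seed_identical_partition(self):
        sim, roi, _ = self._sim(noise=0.5)
        args = (sim.maps["contrast_z"], sim.maps["falff"], sim.maps["gm_modulated"])
        _, _, (v1a, v2a) = split_half_measures(*args, roi.voxels, seed=9,
                                               standardize_falff=False)
        _, _, (v1b, v2b) = split_half_measures(*args, roi.voxels, seed=9,
                                               standardize_falff=False)
        np.testing.assert_array_equal(v1a, v1b)
        np.testing.assert_array_equal(v2a, v2b)

    def test_noiseless_halves_identical(self):
        sim, roi, _ = self._sim(noise=0.0)
        args = (sim.maps["contrast_z"], sim.maps["falff"], sim.maps["gm_modulated"])
        t1, t2, _ = split_half_measures(*args, roi.voxels, seed=1,
                                        standardize_falff=False)
        np.testing.assert_allclose(t1.fs, t2.fs, atol=1e-10)
        assert icc(t1.fs, t2.fs).icc == pytest.approx(1.0, abs=1e-9)

    def test_icc_matches_variance_components_prediction(self):
        """Half-ROI mean noise variance is sigma_v^2/(|ROI|/2); predicted
        split-half ICC is s^2 / (s^2 + 2 sigma_v^2 / |ROI|)."""
        noise, blob = 2.0, 60
        iccs, preds = [], []
        for seed in range(100):
            sim, roi, true_fs = self._sim(noise=noise, blob=blob, seed=seed)
            args = (sim.maps["contrast_z"], sim.maps["falff"], sim.maps["gm_modulated"])
            t1, t2, _ = split_half_measures(*args, roi.voxels, seed=seed,
                                            standardize_falff=False)
            iccs.append(icc(t1.fs, t2.fs).icc)
            s2 = np.var(true_fs)
            preds.append(s2 / (s2 + noise**2 / (blob / 2)))
        assert np.mean(iccs) == pytest.approx(np.mean(preds), abs=0.05)
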