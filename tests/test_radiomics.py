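import itertools

import numpy as np
import pytest

from radiorisk.io import RoiMask, VolumeGrid
from radiorisk.radiomics import (
    DESCRIPTORS,
    FEATURE_FAMILIES,
    HRS6_NAME,
    OFFSETS_13,
    TEXTURE_FAMILIES,
    TextureParams,
    all_feature_names,
    extract_lesion_features,
    extract_roi_features,
    extract_study_features,
    feature_names,
    glcm_3d,
    haralick_features,
    histogram_descriptors,
    hrs6_volume,
    rescale_window,
    texture_maps,
)
from tests.conftest import make_study


# ---------------------------------------------------------------------------
# independent oracles

def glcm_bruteforce(window, n_bins=128, offsets=OFFSETS_13, n_levels=256,
                    symmetric=True):
    """Exhaustive pair-enumeration GLCM oracle (voxel-by-voxel loops)."""
    w = np.asarray(window)
    step = n_levels // n_bins
    counts = np.zeros((n_bins, n_bins))
    for off in offsets:
        for idx in itertools.product(*(range(n) for n in w.shape)):
            jdx = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= j < n for j, n in zip(jdx, w.shape)):
                a, b = int(w[idx]) // step, int(w[jdx]) // step
                counts[a, b] += 1
                if symmetric:
                    counts[b, a] += 1
    return counts / counts.sum()


def haralick_bruteforce(p):
    """Direct-summation Haralick oracle over an explicit normalized matrix."""
    n = p.shape[0]
    energy = entropy = contrast = homogeneity = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            q = p[i, j]
            energy += q * q
            if q > 0:
                entropy -= q * np.log(q)
            contrast += (i - j) ** 2 * q
            homogeneity += q / (1 + (i - j) ** 2)
            mu_i += i * q
            mu_j += j * q
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    if var_i <= 1e-12 or var_j <= 1e-12:
        corr = 0.0
    else:
        cov = sum((i - mu_i) * (j - mu_j) * p[i, j]
                  for i in range(n) for j in range(n))
        corr = cov / np.sqrt(var_i * var_j)
    return {"ene": energy, "ent": entropy, "con": contrast,
            "hom": homogeneity, "cor": corr}


# ---------------------------------------------------------------------------

class TestFeatureNames:
    def test_canonical_counts(self):
        assert len(feature_names()) == 486
        assert len(feature_names("L")) == 162

    def test_printed_examples_present(self):
        names = feature_names()
        assert "L_adc_ene_90" in names
        assert "NATZ_t2_cor_50" in names
        assert "L_t2_int_10" in names
        assert "L_adc_int_Kur" in names

    def test_names_unique_and_deterministic(self):
        names = feature_names()
        assert len(set(names)) == 486
        assert names == feature_names()
        assert all_feature_names()[0] == HRS6_NAME
        assert len(all_feature_names()) == 487

    def test_grammar(self):
        for name in feature_names():
            roi, seq, fam, desc = name.split("_")
            assert roi in ("L", "NAPZ", "NATZ")
            assert seq in ("t2", "adc", "b")
            assert fam in FEATURE_FAMILIES
            assert desc in DESCRIPTORS


class TestHistogramDescriptors:
    def test_constant_input_degenerate_rule(self):
        d = histogram_descriptors([7.0] * 20)
        assert (d.p10, d.p25, d.p50, d.p75, d.p90) == (7, 7, 7, 7, 7)
        assert d.mean == 7 and d.sd == 0
        assert d.skewness == 0 and d.kurtosis == 0

    def test_1_to_100_against_order_statistics(self):
        v = np.arange(1, 101, dtype=float)
        d = histogram_descriptors(v)
        # linear interpolation between order statistics
        assert d.p50 == pytest.approx(50.5)
        assert d.p10 == pytest.approx(10.9)
        assert d.mean == pytest.approx(50.5)
        assert d.sd == pytest.approx(np.std(v, ddof=1))

    def test_symmetric_sample_has_zero_skewness(self):
        d = histogram_descriptors([-3.0, 0.0, 3.0])
        assert d.skewness == pytest.approx(0.0, abs=1e-12)

    def test_percentiles_ordered_on_random_samples(self, rng):
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 50))
            d = histogram_descriptors(v)
            assert d.p10 <= d.p25 <= d.p50 <= d.p75 <= d.p90
            assert d.sd >= 0

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            histogram_descriptors([])


class TestRescaleWindow:
    def test_constant_window_maps_to_zero(self):
        assert np.all(rescale_window(np.full((5, 5, 5), 3.7)) == 0)

    def test_two_valued_window_hits_endpoints(self):
        w = np.full((5, 5, 5), 10.0)
        w[0, 0, 0] = 20.0
        out = rescale_window(w)
        assert out[0, 0, 0] == 255
        assert out[1, 1, 1] == 0

    def test_midpoint_rounds_half_away_from_zero(self):
        w = np.full((5, 5, 5), 10.0)
        w[0, 0, 0] = 20.0
        w[0, 0, 1] = 15.0  # exactly halfway: 127.5 -> 128
        assert rescale_window(w)[0, 0, 1] == 128

    def test_bounds(self, rng):
        out = rescale_window(rng.normal(size=(5, 5, 5)))
        assert out.min() >= 0 and out.max() == 255


class TestGlcm:
    def test_constant_window_single_entry(self):
        g = glcm_3d(np.zeros((5, 5, 5), int))
        assert g.matrix[0, 0] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_symmetrized_matrix_equals_transpose(self, rng):
        w = rng.integers(0, 256, (5, 5, 5))
        g = glcm_3d(w)
        np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-15)

    def test_toy_window_single_offset_vs_enumeration(self):
        w = np.array([[[0, 255], [128, 64]], [[255, 0], [64, 192]]])
        g = glcm_3d(w, offsets=((1, 0, 0),))
        oracle = glcm_bruteforce(w, offsets=((1, 0, 0),))
        np.testing.assert_allclose(g.matrix, oracle, atol=1e-12)

    def test_empty_offsets_fail(self):
        with pytest.raises(ValueError, match="offset"):
            glcm_3d(np.zeros((5, 5, 5), int), offsets=())

    def test_out_of_range_values_fail(self):
        with pytest.raises(ValueError, match="255"):
            glcm_3d(np.full((3, 3, 3), 300))


class TestHaralick:
    def test_constant_window_closed_form(self):
        h = haralick_features(glcm_3d(np.zeros((5, 5, 5), int)))
        assert h["ene"] == pytest.approx(1.0)
        assert h["ent"] == pytest.approx(0.0)
        assert h["con"] == pytest.approx(0.0)
        assert h["hom"] == pytest.approx(1.0)
        assert h["cor"] == 0.0  # zero-variance rule

    def test_uniform_matrix_closed_form(self):
        from radiorisk.radiomics import GlcmMatrix
        k = 8
        p = np.zeros((128, 128))
        p[:k, :k] = 1.0 / k**2
        h = haralick_features(GlcmMatrix(p, 128, ((1, 0, 0),)))
        assert h["ene"] == pytest.approx(1.0 / k**2)
        assert h["ent"] == pytest.approx(np.log(k**2))

    def test_toy_matrix_direct_summation(self):
        from radiorisk.radiomics import GlcmMatrix
        p = np.zeros((128, 128))
        p[0, 0], p[0, 1], p[1, 0], p[1, 1], p[2, 2] = 0.2, 0.15, 0.15, 0.3, 0.2
        g = GlcmMatrix(p, 128, ((1, 0, 0),))
        h = haralick_features(g)
        oracle = haralick_bruteforce(p)
        for k in h:
            assert h[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        from radiorisk.radiomics import GlcmMatrix
        with pytest.raises(ValueError, match="sum 1"):
            GlcmMatrix(np.ones((128, 128)), 128, ((1, 0, 0),))


class TestOracleEquivalence:
    def test_random_windows_match_bruteforce(self, rng):
        """Pipeline GLCM+Haralick vs exhaustive enumeration, 20 random windows."""
        for _ in range(20):
            w = rng.integers(0, 256, (5, 5, 5))
            g = glcm_3d(w)
            oracle_m = glcm_bruteforce(w)
            np.testing.assert_allclose(g.matrix, oracle_m, atol=1e-12)
            h = haralick_features(g)
            ho = haralick_bruteforce(oracle_m)
            for k in h:
                assert h[k] == pytest.approx(ho[k], abs=1e-10)


class TestTextureMaps:
    def _volume(self, vals):
        return VolumeGrid(vals, (1, 1, 1), "t2")

    def test_homogeneous_volume_energy_one_contrast_zero(self):
        vol = self._volume(np.full((12, 12, 12), 42.0))
        roi = RoiMask(np.ones((12, 12, 12), bool), "L", "1")
        maps = texture_maps(vol, roi)
        np.testing.assert_allclose(maps["ene"][roi.mask], 1.0)
        np.testing.assert_allclose(maps["con"][roi.mask], 0.0)

    def test_compositionality_with_single_window_path(self, rng):
        vals = rng.normal(100, 15, (12, 12, 12))
        mask = np.zeros((12, 12, 12), bool)
        mask[6, 6, 6] = True
        maps = texture_maps(self._volume(vals), RoiMask(mask, "L", "1"))
        w = vals[4:9, 4:9, 4:9]
        h = haralick_features(glcm_3d(rescale_window(w)))
        for fam in TEXTURE_FAMILIES:
            assert maps[fam][6, 6, 6] == pytest.approx(h[fam], abs=1e-10)

    def test_boundary_window_uses_clipped_context(self, rng):
        vals = rng.normal(100, 15, (10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[0, 0, 0] = True
        maps = texture_maps(self._volume(vals), RoiMask(mask, "L", "1"))
        h = haralick_features(glcm_3d(rescale_window(vals[:3, :3, :3])))
        for fam in TEXTURE_FAMILIES:
            assert maps[fam][0, 0, 0] == pytest.approx(h[fam], abs=1e-10)

    def test_checkerboard_has_higher_contrast_than_smooth_noise(self, rng):
        from scipy.ndimage import gaussian_filter
        shape = (14, 14, 14)
        idx = np.indices(shape).sum(axis=0)
        checker = (idx % 2).astype(float)
        smooth = gaussian_filter(rng.standard_normal(shape), 1.5)
        smooth = (smooth - smooth.mean()) / smooth.std() * checker.std()
        roi = np.zeros(shape, bool)
        roi[4:10, 4:10, 4:10] = True
        m_checker = texture_maps(self._volume(checker), RoiMask(roi, "L", "1"))
        m_smooth = texture_maps(self._volume(smooth), RoiMask(roi, "L", "1"))
        assert (np.nanmean(m_checker["con"]) > np.nanmean(m_smooth["con"]))

    def test_translation_invariance_of_textures(self, rng):
        vals = rng.normal(50, 10, (12, 12, 12))
        roi = np.zeros((12, 12, 12), bool)
        roi[4:8, 4:8, 4:8] = True
        m1 = texture_maps(self._volume(vals), RoiMask(roi, "L", "1"))
        m2 = texture_maps(self._volume(vals + 1000.0), RoiMask(roi, "L", "1"))
        for fam in TEXTURE_FAMILIES:
            np.testing.assert_allclose(m1[fam][roi], m2[fam][roi], atol=1e-9)

    def test_empty_roi_fails(self):
        vol = self._volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="non-empty"):
            texture_maps(vol, RoiMask(np.zeros((8, 8, 8), bool), "L", "1"))


class TestHrs6Volume:
    @pytest.mark.parametrize("n_vox,spacing,expected", [
        (1000, (1, 1, 1), 1.0),
        (0, (1, 1, 1), 0.0),
        (250, (0.5, 0.5, 3.0), 0.1875),
    ])
    def test_volume_arithmetic(self, n_vox, spacing, expected):
        mask = np.zeros((20, 20, 20), bool)
        mask.ravel()[:n_vox] = True
        assert hrs6_volume(RoiMask(mask, "L", "1"), spacing) == pytest.approx(expected)


class TestExtraction:
    def test_roi_feature_name_set(self, study):
        feats = extract_roi_features(study, study.mask("NAPZ"))
        assert set(feats) == set(feature_names("NAPZ"))

    def test_lesion_median_intensity_definition(self, study):
        feats = extract_roi_features(study, study.mask("L", "1"), role="L")
        lesion = study.mask("L", "1")
        expected = np.median(study.volumes["adc"].values[lesion.mask])
        assert feats["L_adc_int_50"] == pytest.approx(expected)

    def test_full_vector_canonical_and_finite(self, study):
        feats = extract_lesion_features(study, "1")
        assert list(feats) == all_feature_names()
        assert all(np.isfinite(v) for v in feats.values())
        assert feats[HRS6_NAME] > 0

    def test_translation_shifts_only_intensity_location(self, study):
        feats = extract_roi_features(study, study.mask("L", "1"), role="L")
        shifted = make_study()
        for seq in shifted.volumes:
            v = shifted.volumes[seq]
            shifted.volumes[seq] = VolumeGrid(v.values + 500.0, v.spacing, seq)
        feats2 = extract_roi_features(shifted, shifted.mask("L", "1"), role="L")
        for name in feats:
            fam, desc = name.split("_")[2], name.split("_")[3]
            if fam != "int":
                assert feats2[name] == pytest.approx(feats[name], abs=1e-9)
            elif desc in ("SD", "Kur", "Ske"):
                assert feats2[name] == pytest.approx(feats[name], abs=1e-9)
            else:  # location statistics shift by exactly the offset
                assert feats2[name] == pytest.approx(feats[name] + 500.0, rel=1e-9)

    def test_extraction_is_deterministic(self, study):
        f1 = extract_lesion_features(study, "1")
        f2 = extract_lesion_features(study, "1")
        assert f1 == f2

    def test_too_small_roi_fails(self, study):
        tiny = np.zeros(study.shape, bool)
        tiny[0, 0, 0] = True
        with pytest.raises(ValueError, match="minimum"):
            extract_roi_features(study, RoiMask(tiny, "L", "1"), role="L")

    def test_study_extraction_shares_nat_features(self, study):
        per_lesion = extract_study_features(study)
        assert set(per_lesion) == {"1"}
        single = extract_lesion_features(study, "1")
        assert per_lesion["1"] == single
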