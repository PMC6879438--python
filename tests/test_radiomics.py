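import numpy as np
import pytest

from mclrad.radiomics import (
    DIRECTIONS_13,
    TEXTURE_FEATURE_NAMES,
    GLCMSet,
    QuantizedVolume,
    extract_all,
    features_from_matrix,
    first_order,
    glcm_3d,
    quantize,
    texture_features,
)
from mclrad.volumes import PETVolume

from ._oracles import glcm_counts_bruteforce, texture_features_literal
from .conftest import random_masked_volume


class TestFirstOrder:
    def test_two_voxel_arithmetic(self):
        # voxel volume 0.1 mL wants spacing with dx*dy*dz = 100 mm^3
        vol = PETVolume(np.array([[[2.0, 4.0]]]), (10.0, 5.0, 2.0))
        mask = np.ones((1, 1, 2), dtype=bool)
        fo = first_order(vol, mask)
        assert fo.suv_mean == pytest.approx(3.0)
        assert fo.suv_max == pytest.approx(4.0)
        assert fo.tmtv_ml == pytest.approx(0.2)
        assert fo.tlg == pytest.approx(0.6)

    def test_tlg_is_exactly_tmtv_times_suvmean(self, rng, spacing_pet):
        for _ in range(20):
            grid = rng.random((6, 6, 6)) * 10
            mask = rng.random((6, 6, 6)) < 0.4
            if not mask.any():
                continue
            fo = first_order(PETVolume(grid, spacing_pet), mask)
            assert fo.tlg == fo.tmtv_ml * fo.suv_mean  # bit-wise identity

    def test_uniform_volume_peak_equals_value(self, spacing_pet):
        vol = PETVolume(np.full((8, 8, 8), 4.2), spacing_pet)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        fo = first_order(vol, mask)
        assert fo.suv_peak == pytest.approx(4.2)
        assert fo.suv_mean <= fo.suv_max
        assert fo.suv_peak <= fo.suv_max

    def test_hot_voxel_peak_matches_enumerated_sphere(self, spacing_pet):
        # at 5.5 x 5.5 x 3.3 mm spacing, a 1 mL sphere (r = 6.20 mm) covers
        # the centre, 4 in-plane face neighbours and 2 axial neighbours: 7 voxels
        grid = np.ones((9, 9, 9))
        grid[4, 4, 4] = 10.0
        vol = PETVolume(grid, spacing_pet)
        mask = np.zeros_like(grid, dtype=bool)
        mask[4, 4, 4] = True
        fo = first_order(vol, mask)
        assert fo.suv_peak == pytest.approx((10 + 6 * 1) / 7)

    def test_empty_mask_rejected(self, spacing_pet):
        vol = PETVolume(np.ones((3, 3, 3)), spacing_pet)
        with pytest.raises(ValueError, match="empty"):
            first_order(vol, np.zeros((3, 3, 3), dtype=bool))


class TestQuantize:
    def test_constant_region_all_level_one(self, spacing_pet):
        vol = PETVolume(np.full((4, 4, 4), 3.3), spacing_pet)
        mask = np.ones((4, 4, 4), dtype=bool)
        for g in (2, 16, 64):
            q = quantize(vol, mask, g)
            assert np.all(q.levels[mask] == 1)

    def test_midpoint_split_for_two_bins(self, spacing_pet):
        vol = PETVolume(np.array([[[0.0, 1.0, 2.0, 3.0]]]), spacing_pet)
        mask = np.ones((1, 1, 4), dtype=bool)
        q = quantize(vol, mask, 2)
        np.testing.assert_array_equal(q.levels[0, 0], [1, 1, 2, 2])

    def test_levels_span_range_and_extremes_map_to_ends(self, rng, spacing_pet):
        grid = rng.random((6, 6, 6)) * 9
        mask = rng.random((6, 6, 6)) < 0.7
        vol = PETVolume(grid, spacing_pet)
        q = quantize(vol, mask, 64)
        lv = q.levels[mask]
        assert lv.min() >= 1 and lv.max() <= 64
        assert q.levels[np.unravel_index(np.argmax(np.where(mask, grid, -1)), grid.shape)] == 64
        assert q.levels[np.unravel_index(np.argmin(np.where(mask, grid, 1e9)), grid.shape)] == 1

    def test_too_few_bins_rejected(self, spacing_pet):
        vol = PETVolume(np.ones((2, 2, 2)), spacing_pet)
        with pytest.raises(ValueError):
            quantize(vol, np.ones((2, 2, 2), dtype=bool), 1)


class TestGLCM3D:
    def test_two_voxel_hand_enumeration(self):
        levels = np.zeros((2, 1, 1), dtype=np.int32)
        levels[0, 0, 0], levels[1, 0, 0] = 1, 2
        mask = np.ones((2, 1, 1), dtype=bool)
        q = QuantizedVolume(levels=levels, n_bins=2, mask=mask)
        glcms = glcm_3d(q)
        d_x = DIRECTIONS_13.index((1, 0, 0))
        np.testing.assert_array_equal(glcms.matrices[d_x], [[0, 1], [1, 0]])
        assert glcms.pair_counts[d_x] == 1
        for d in range(13):
            if d != d_x:
                assert glcms.pair_counts[d] == 0

    def test_constant_cube_concentrates_on_diagonal(self, spacing_pet):
        vol = PETVolume(np.full((4, 4, 4), 2.0), spacing_pet)
        mask = np.ones((4, 4, 4), dtype=bool)
        glcms = glcm_3d(quantize(vol, mask, 8))
        for d in range(13):
            m = glcms.matrices[d].astype(float)
            assert m.sum() > 0
            assert m[0, 0] == m.sum()  # p(1,1) = 1 after normalization

    def test_counts_match_allpairs_enumeration(self, rng):
        for _ in range(25):
            levels, mask, n_bins = random_masked_volume(rng)
            q = QuantizedVolume(levels=levels, n_bins=n_bins, mask=mask)
            glcms = glcm_3d(q)
            for d, direction in enumerate(DIRECTIONS_13):
                expect, n_pairs = glcm_counts_bruteforce(levels, mask, direction, n_bins)
                np.testing.assert_array_equal(glcms.matrices[d], expect)
                assert glcms.pair_counts[d] == n_pairs

    def test_matrices_are_symmetric_and_normalizable(self, rng):
        levels, mask, n_bins = random_masked_volume(rng)
        glcms = glcm_3d(QuantizedVolume(levels=levels, n_bins=n_bins, mask=mask))
        for d in range(13):
            m = glcms.matrices[d]
            np.testing.assert_array_equal(m, m.T)
            if m.sum():
                assert abs(m / m.sum() - (m / m.sum()).T).max() == 0
                assert (m / m.sum()).sum() == pytest.approx(1.0, abs=1e-12)


class TestTextureFeatures:
    def test_constant_region_identities(self, spacing_pet):
        vol = PETVolume(np.full((5, 5, 5), 7.0), spacing_pet)
        mask = np.ones((5, 5, 5), dtype=bool)
        tex = texture_features(glcm_3d(quantize(vol, mask, 16)))
        assert tex.entropy == pytest.approx(0.0, abs=1e-12)
        assert tex.angular_second_moment == pytest.approx(1.0)
        assert tex.contrast == pytest.approx(0.0, abs=1e-12)
        assert tex.homogeneity == pytest.approx(1.0)
        assert tex.maximum_probability == pytest.approx(1.0)
        assert tex.cluster_shade == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_matrix_closed_forms(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = features_from_matrix(p)
        assert f["entropy"] == pytest.approx(1.0)       # 1 bit
        assert f["contrast"] == pytest.approx(1.0)
        assert f["angular_second_moment"] == pytest.approx(0.5)
        assert f["maximum_probability"] == pytest.approx(0.5)
        assert f["sum_average"] == pytest.approx(3.0)
        assert f["imc1"] == pytest.approx(-1.0)

    def test_features_match_literal_formula_oracle(self, rng):
        for _ in range(30):
            g = int(rng.integers(2, 9))
            m = rng.random((g, g))
            m = m + m.T
            p = m / m.sum()
            ours = features_from_matrix(p)
            oracle = texture_features_literal(p)
            for name in TEXTURE_FEATURE_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_grey_level_reversal_symmetries(self, rng):
        g = 6
        m = rng.random((g, g))
        m = m + m.T
        p = m / m.sum()
        f = features_from_matrix(p)
        f_rev = features_from_matrix(p[::-1, ::-1])
        for name in ("entropy", "angular_second_moment", "contrast",
                     "homogeneity", "maximum_probability"):
            assert f_rev[name] == pytest.approx(f[name], abs=1e-12)
        assert f_rev["cluster_shade"] == pytest.approx(-f["cluster_shade"], abs=1e-12)

    def test_min_pairs_rule_excludes_and_errors(self):
        levels = np.zeros((2, 1, 1), dtype=np.int32)
        levels[0, 0, 0], levels[1, 0, 0] = 1, 2
        mask = np.ones((2, 1, 1), dtype=bool)
        glcms = glcm_3d(QuantizedVolume(levels=levels, n_bins=2, mask=mask))
        with pytest.raises(ValueError, match="minimum of 20"):
            texture_features(glcms, min_pairs=20)
        tex = texture_features(glcms, min_pairs=1)
        assert tex.n_valid_directions == 1

    def test_invariant_ranges_on_random_fixtures(self, rng):
        for _ in range(10):
            levels, mask, n_bins = random_masked_volume(rng)
            glcms = glcm_3d(QuantizedVolume(levels=levels, n_bins=n_bins, mask=mask))
            if not glcms.valid(1).any():
                continue
            tex = texture_features(glcms, min_pairs=1)
            assert tex.entropy >= 0
            assert 0 < tex.angular_second_moment <= 1
            assert 0 < tex.maximum_probability <= 1
            assert tex.contrast >= 0
            assert 0 < tex.homogeneity <= 1
            assert -1 <= tex.imc1 <= 0 + 1e-12
            assert 0 <= tex.imc2 < 1


class TestExtractAll:
    def test_homogeneous_lesion_entropy_zero_and_mean(self, spacing_pet):
        grid = np.full((6, 6, 6), 0.5)
        grid[1:5, 1:5, 1:5] = 4.0
        vol = PETVolume(grid, spacing_pet)
        mask = grid == 4.0
        row = extract_all(vol, mask, min_pairs=1)
        assert row["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert row["angular_second_moment"] == pytest.approx(1.0)
        assert row["suv_mean"] == pytest.approx(4.0)

    def test_extraction_is_deterministic(self, rng, spacing_pet):
        grid = rng.random((8, 8, 8)) * 6 + 0.5
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:7, 1:7, 1:7] = True
        vol = PETVolume(grid, spacing_pet)
        r1 = extract_all(vol, mask)
        r2 = extract_all(vol, mask)
        assert r1 == r2
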