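"""Texture-matrix families against hand computations and brute-force
enumeration, plus shape features and the feature manifest."""

import numpy as np
import pytest

import habikit as hk
from habikit.texture import (
    OFFSETS_13,
    discretize,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    load_manifest,
    ngtdm_features,
    ngtdm_table,
    shape_features,
)
from habikit.texture.matrices import _rlm_style_features, _GLRLM_NAMES
from conftest import (
    glcm_bruteforce,
    gldm_bruteforce,
    glrlm_bruteforce,
    glszm_bruteforce,
)


def _disc_from(levels, mask=None):
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    from habikit.texture.discretize import DiscretizedVolume

    return DiscretizedVolume(levels=levels, mask=np.asarray(mask, bool),
                             n_levels=int(levels.max()), rule="test")


class TestGLCM:
    def test_checkerboard_matches_hand_computation(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1  # levels 1/2
        disc = _disc_from(board.reshape(1, 4, 4))
        offset = (0, 0, 1)
        mat = glcm_matrix(disc, offset)
        # 4 rows x 3 horizontal pairs, all (1,2) or (2,1); symmetric: 24 total
        np.testing.assert_array_equal(mat, [[0, 12], [12, 0]])
        p = mat / mat.sum()
        # hand values: Idn = 1/(1+1/2); Correlation = -1; CP = 0
        idn_hand = (p[0, 1] + p[1, 0]) / (1 + 1 / 2)
        from habikit.texture.matrices import _glcm_features_single

        feats = _glcm_features_single(p)
        assert feats["Idn"] == pytest.approx(idn_hand)
        assert feats["Correlation"] == pytest.approx(-1.0)
        assert feats["ClusterProminence"] == pytest.approx(0.0)

    def test_single_level_conventions(self):
        disc = _disc_from(np.ones((3, 3, 3), dtype=int))
        feats = glcm_features(disc)
        assert feats["Idn"] == pytest.approx(1.0)
        assert feats["Correlation"] == pytest.approx(1.0)
        assert feats["Contrast"] == pytest.approx(0.0)

    def test_matrix_symmetric_and_matches_bruteforce(self, rng):
        levels = rng.integers(1, 5, size=(5, 5, 5)).astype(np.int32)
        mask = rng.uniform(size=levels.shape) < 0.8
        levels[~mask] = 0
        disc = _disc_from(levels, mask)
        for offset in [(0, 0, 1), (1, -1, 0), (1, 1, 1)]:
            mat = glcm_matrix(disc, offset)
            np.testing.assert_array_equal(mat, mat.T)
            np.testing.assert_array_equal(
                mat, glcm_bruteforce(levels, mask, offset, disc.n_levels)
            )


class TestGLRLM:
    def test_hand_run_enumeration_1d(self):
        row = np.array([1, 1, 2, 2, 2]).reshape(1, 1, 5)
        disc = _disc_from(row)
        mat = glrlm_matrix(disc, (0, 0, 1))
        expected = np.zeros((2, 3))
        expected[0, 1] = 1  # level 1, length 2
        expected[1, 2] = 1  # level 2, length 3
        np.testing.assert_array_equal(mat, expected)
        feats = _rlm_style_features(mat, disc.n_voxels, _GLRLM_NAMES)
        srlgle_hand = (1 / (1 * 4) + 1 / (4 * 9)) / 2
        assert feats["ShortRunLowGrayLevelEmphasis"] == pytest.approx(
            srlgle_hand)

    def test_constant_volume_single_run_glnn_one(self):
        disc = _disc_from(np.ones((1, 1, 6), dtype=int))
        mat = glrlm_matrix(disc, (0, 0, 1))
        assert mat.sum() == 1
        feats = _rlm_style_features(mat, disc.n_voxels, _GLRLM_NAMES)
        assert feats["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)

    def test_matches_bruteforce_all_directions(self, rng):
        levels = rng.integers(1, 4, size=(4, 5, 4)).astype(np.int32)
        mask = rng.uniform(size=levels.shape) < 0.75
        levels[~mask] = 0
        mask[2, 2, 2] = True
        levels[2, 2, 2] = 1
        disc = _disc_from(levels, mask)
        for direction in OFFSETS_13:
            a = glrlm_matrix(disc, direction)
            b = glrlm_bruteforce(levels, mask, direction, disc.n_levels)
            np.testing.assert_array_equal(a, b)

    def test_run_total_conserves_voxel_count(self, rng):
        levels = rng.integers(1, 3, size=(6, 6, 6)).astype(np.int32)
        disc = _disc_from(levels)
        for direction in OFFSETS_13:
            mat = glrlm_matrix(disc, direction)
            lengths = np.arange(1, mat.shape[1] + 1)
            assert (mat * lengths).sum() == disc.n_voxels


class TestGLSZM:
    def test_two_zone_hand_computation(self):
        vol = np.zeros((1, 1, 5), dtype=np.int32)
        vol[0, 0, :2] = 1  # level-1 zone of size 2
        vol[0, 0, 2:] = 2  # level-2 zone of size 3
        disc = _disc_from(vol)
        feats = glszm_features(disc)
        nz = 2
        sznn_hand = (1 ** 2 + 1 ** 2) / nz ** 2
        sahgle_hand = (1 * 1 / 4 + 4 * 1 / 9) / nz
        lalgle_hand = (1 * 4 / 1 + 1 * 9 / 4) / nz
        assert feats["SizeZoneNonUniformityNormalized"] == pytest.approx(
            sznn_hand)
        assert feats["SmallAreaHighGrayLevelEmphasis"] == pytest.approx(
            sahgle_hand)
        assert feats["LargeAreaLowGrayLevelEmphasis"] == pytest.approx(
            lalgle_hand)

    def test_constant_volume_single_zone(self):
        disc = _disc_from(np.ones((3, 3, 3), dtype=int))
        feats = glszm_features(disc)
        assert feats["SizeZoneNonUniformityNormalized"] == pytest.approx(1.0)
        assert feats["ZonePercentage"] == pytest.approx(1 / 27)

    def test_matches_floodfill_bruteforce(self, rng):
        levels = rng.integers(1, 4, size=(5, 5, 5)).astype(np.int32)
        mask = rng.uniform(size=levels.shape) < 0.7
        levels[~mask] = 0
        mask[2, 2, 2] = True
        levels[2, 2, 2] = 2
        disc = _disc_from(levels, mask)
        a = glszm_matrix(disc)
        b = glszm_bruteforce(levels, mask, disc.n_levels)
        np.testing.assert_array_equal(a, b)

    def test_zone_total_conserves_voxel_count(self, rng):
        levels = rng.integers(1, 5, size=(6, 6, 6)).astype(np.int32)
        disc = _disc_from(levels)
        mat = glszm_matrix(disc)
        sizes = np.arange(1, mat.shape[1] + 1)
        assert (mat * sizes).sum() == disc.n_voxels


class TestGLDM:
    def test_constant_cube_center_dependence_26(self):
        disc = _disc_from(np.ones((3, 3, 3), dtype=int))
        mat = gldm_matrix(disc)
        assert mat[0, 26] == 1  # only the centre has all 26 neighbours equal
        assert mat.sum() == 27

    def test_two_level_toy_matches_bruteforce(self, rng):
        levels = rng.integers(1, 3, size=(4, 4, 4)).astype(np.int32)
        mask = rng.uniform(size=levels.shape) < 0.85
        levels[~mask] = 0
        mask[1, 1, 1] = True
        levels[1, 1, 1] = 1
        disc = _disc_from(levels, mask)
        for alpha in (0, 1):
            np.testing.assert_array_equal(
                gldm_matrix(disc, alpha=alpha),
                gldm_bruteforce(levels, mask, disc.n_levels, alpha=alpha),
            )

    def test_dependence_total_counts_each_voxel_once(self, rng):
        levels = rng.integers(1, 4, size=(5, 6, 5)).astype(np.int32)
        disc = _disc_from(levels)
        assert gldm_matrix(disc).sum() == disc.n_voxels

    def test_ldlgle_formula(self):
        disc = _disc_from(np.ones((3, 3, 3), dtype=int))
        feats = gldm_features(disc)
        mat = gldm_matrix(disc)
        d = np.arange(27.0)
        hand = (mat[0] * d ** 2 / 1.0).sum() / mat.sum()
        assert feats["LargeDependenceLowGrayLevelEmphasis"] == pytest.approx(
            hand)


class TestNGTDM:
    def test_constant_volume_zero_contrast(self):
        disc = _disc_from(np.ones((4, 4, 4), dtype=int))
        feats = ngtdm_features(disc)
        assert feats["Contrast"] == 0.0

    def test_s_column_matches_hand_computation(self):
        vol = np.ones((1, 1, 4), dtype=np.int32)
        vol[0, 0, 2:] = 2  # [1,1,2,2]
        disc = _disc_from(vol)
        n_i, s_i = ngtdm_table(disc)
        # neighbour means: v0:1, v1:(1+2)/2=1.5, v2:(1+2)/2=1.5, v3:2
        np.testing.assert_allclose(n_i, [2, 2])
        np.testing.assert_allclose(s_i, [abs(1 - 1) + abs(1 - 1.5),
                                         abs(2 - 1.5) + abs(2 - 2)])

    def test_fine_checkerboard_less_coarse_than_blocks(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        fine = (idx % 2 + 1).astype(np.int32)
        blocks = np.ones((6, 6, 6), dtype=np.int32)
        blocks[3:, :, :] = 2
        c_fine = ngtdm_features(_disc_from(fine))["Coarseness"]
        c_blocks = ngtdm_features(_disc_from(blocks))["Coarseness"]
        assert c_fine < c_blocks


class TestShape:
    def test_cube_voxel_volume(self):
        cube = np.zeros((14, 14, 14))
        cube[2:12, 2:12, 2:12] = 1
        feats = shape_features(hk.TumorMask(cube))
        assert feats["VoxelVolume"] == pytest.approx(1000.0)
        assert feats["Maximum3DDiameter"] == pytest.approx(
            9 * np.sqrt(3), rel=1e-6)

    def test_digital_ball_sphericity_near_one(self):
        ax = np.arange(25) - 12
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = (np.sqrt(zz ** 2 + yy ** 2 + xx ** 2) <= 10).astype(float)
        feats = shape_features(hk.TumorMask(ball))
        assert abs(feats["Sphericity"] - 1.0) < 0.10
        assert feats["Elongation"] == pytest.approx(1.0, abs=0.02)

    def test_sphericity_bounded_by_one(self, rng):
        for _ in range(5):
            blob = rng.uniform(size=(8, 8, 8)) < 0.5
            blob[4, 4, 4] = True
            from scipy import ndimage

            blob = ndimage.binary_closing(blob)
            blob[4, 4, 4] = True
            feats = shape_features(hk.TumorMask(blob.astype(float)))
            assert feats["Sphericity"] <= 1.0 + 0.05  # discretization slack


class TestManifest:
    def test_default_manifest_totals_1218(self):
        man = load_manifest("default")
        assert man.total_per_region == 1218
        assert len(man.feature_names()) == 1218
        assert len(set(man.feature_names())) == 1218

    def test_published_model_features_resolve_in_manifest(self):
        man = load_manifest("default")
        names = set(man.feature_names())
        for model_name in ("paper_voi", "paper_sub"):
            model = hk.load_paper_model(model_name)
            for feat in model.coefficients:
                base = feat.split("_", 1)[1] if feat.startswith("Sub") else feat
                assert base in names, feat

    def test_shape_features_identical_across_filters(self, small_cohort):
        """Shape depends on the mask only: the manifest computes it once
        under the `original` prefix, never per filter."""
        man = load_manifest("small")
        _, volumes, _, _ = small_cohort
        feats = hk.extract_region(volumes[0][0], volumes[0][1], man)
        shape_cols = [c for c in feats if "_shape_" in c]
        assert all(c.startswith("original_shape_") for c in shape_cols)
        assert len(shape_cols) == 14
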