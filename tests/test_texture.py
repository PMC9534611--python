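"""Texture families against independent brute-force oracles plus the
spec-level hand-enumerable cases."""

import numpy as np
import pytest

import oracles
from wavemics import (
    FAMILY_SIZES,
    ImageVolume,
    ROIMask,
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from wavemics.texture import (
    DIRECTIONS_13,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
    _glcm_stats,
    _rl_style_stats,
    GLSZM_FEATURE_NAMES,
)


def droi_from_levels(level_array, mask=None):
    arr = np.asarray(level_array, dtype=float) * 10.0
    vol = ImageVolume(arr, (1.0, 1.0, 1.0))
    m = ROIMask(np.ones(arr.shape, bool) if mask is None else mask)
    return discretize(vol, m, bin_width=10.0)


def constant_droi(shape=(3, 3, 3)):
    return droi_from_levels(np.zeros(shape))


class TestMatrixOracles:
    """Exhaustive-enumeration equivalence on small random ROIs."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_glcm_matrices_and_stats(self, seed):
        rng = np.random.default_rng(seed)
        droi = self._random_droi(rng)
        for off in DIRECTIONS_13:
            mine = glcm_matrix(droi, off)
            ref = oracles.glcm_matrix_bf(droi.levels, droi.mask, droi.n_levels, off)
            np.testing.assert_allclose(mine, ref, atol=1e-12)
            if mine.sum() > 0:
                stats = _glcm_stats(mine)
                ref_stats = oracles.glcm_stats_bf(ref)
                for k, v in ref_stats.items():
                    assert stats[k] == pytest.approx(v, abs=1e-10), k

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_glrlm_matrices_and_stats(self, seed):
        rng = np.random.default_rng(seed)
        droi = self._random_droi(rng)
        n_vox = int(droi.mask.sum())
        for off in DIRECTIONS_13:
            mine = glrlm_matrix(droi, off)
            ref = oracles.glrlm_matrix_bf(droi.levels, droi.mask, droi.n_levels, off)
            np.testing.assert_allclose(mine, ref, atol=1e-12)
            stats = _rl_style_stats(mine, n_vox, (), "Run")
            for k, v in oracles.rl_stats_bf(ref, n_vox, "Run").items():
                assert stats[k] == pytest.approx(v, abs=1e-10), k

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_glszm_matrix_and_stats(self, seed):
        rng = np.random.default_rng(seed)
        droi = self._random_droi(rng)
        n_vox = int(droi.mask.sum())
        mine = glszm_matrix(droi)
        ref = oracles.glszm_matrix_bf(droi.levels, droi.mask, droi.n_levels)
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        stats = _rl_style_stats(mine, n_vox, GLSZM_FEATURE_NAMES, "Zone")
        for k, v in oracles.rl_stats_bf(ref, n_vox, "Zone").items():
            assert stats[k] == pytest.approx(v, abs=1e-10), k

    @pytest.mark.parametrize("seed", [9, 10, 11])
    def test_gldm_matrix_and_stats(self, seed):
        rng = np.random.default_rng(seed)
        droi = self._random_droi(rng)
        mine = gldm_matrix(droi)
        ref = oracles.gldm_matrix_bf(droi.levels, droi.mask, droi.n_levels)
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        feats = gldm_features(droi)
        for k, v in oracles.gldm_stats_bf(ref).items():
            assert feats[k] == pytest.approx(v, abs=1e-10), k

    @pytest.mark.parametrize("seed", [12, 13, 14])
    def test_ngtdm_table_and_stats(self, seed):
        rng = np.random.default_rng(seed)
        droi = self._random_droi(rng)
        n_i, s_i, nv = ngtdm_table(droi)
        rn, rs, rv = oracles.ngtdm_table_bf(droi.levels, droi.mask, droi.n_levels)
        np.testing.assert_allclose(n_i, rn, atol=1e-12)
        np.testing.assert_allclose(s_i, rs, atol=1e-10)
        assert nv == rv
        feats = ngtdm_features(droi)
        for k, v in oracles.ngtdm_stats_bf(rn, rs, rv).items():
            assert feats[k] == pytest.approx(v, abs=1e-10), k

    @staticmethod
    def _random_droi(rng):
        vals = rng.integers(0, 4, size=(4, 4, 4)).astype(float)
        mask = rng.random((4, 4, 4)) < 0.8
        if not mask.any():
            mask[0, 0, 0] = True
        return droi_from_levels(vals, mask)


class TestHandCases:
    def test_glcm_constant_roi(self):
        feats = glcm_features(constant_droi())
        assert feats["Correlation"] == 1.0  # documented degenerate sentinel
        assert feats["JointEnergy"] == pytest.approx(1.0)
        assert feats["Contrast"] == 0.0

    def test_glcm_checkerboard_single_direction(self):
        levels = np.indices((1, 1, 6)).sum(axis=0) % 2  # alternate along x
        droi = droi_from_levels(levels)
        feats = glcm_features(droi, directions=((0, 0, 1),))
        assert feats["Contrast"] == pytest.approx(1.0)
        assert feats["JointEnergy"] == pytest.approx(0.5)

    def test_glrlm_constant_roi_single_direction(self):
        droi = constant_droi((3, 3, 3))
        P = glrlm_matrix(droi, (0, 0, 1))
        # one run of length 3 per (z, y) line
        assert P.shape == (1, 3)
        assert P[0, 2] == 9 and P.sum() == 9
        feats = glrlm_features(droi, directions=((0, 0, 1),))
        assert feats["RunPercentage"] == pytest.approx(9 / 27)

    def test_glszm_constant_roi_single_zone(self):
        droi = constant_droi((3, 3, 3))
        feats = glszm_features(droi)
        assert feats["ZonePercentage"] == pytest.approx(1 / 27)

    def test_family_sizes(self, droi_factory):
        droi = droi_factory()
        assert len(glcm_features(droi)) == FAMILY_SIZES["glcm"]
        assert len(glrlm_features(droi)) == FAMILY_SIZES["glrlm"]
        assert len(glszm_features(droi)) == FAMILY_SIZES["glszm"]
        assert len(gldm_features(droi)) == FAMILY_SIZES["gldm"]
        assert len(ngtdm_features(droi)) == FAMILY_SIZES["ngtdm"]


class TestMatrixInvariants:
    def test_glcm_normalized_and_symmetric(self, droi_factory):
        droi = droi_factory(shape=(5, 5, 5))
        for off in DIRECTIONS_13:
            P = glcm_matrix(droi, off)
            if P.sum() > 0:
                assert P.sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_translation_invariance(self, rng):
        vals = rng.integers(0, 5, size=(4, 4, 4)).astype(float)
        mask = np.zeros((8, 8, 8), bool)
        big = np.zeros((8, 8, 8))
        big[1:5, 1:5, 1:5] = vals
        mask[1:5, 1:5, 1:5] = True
        big2 = np.roll(big, (2, 1, 3), axis=(0, 1, 2))
        mask2 = np.roll(mask, (2, 1, 3), axis=(0, 1, 2))
        d1 = discretize(ImageVolume(big, (1, 1, 1)), ROIMask(mask), 1.0)
        d2 = discretize(ImageVolume(big2, (1, 1, 1)), ROIMask(mask2), 1.0)
        for fn in (glcm_features, glrlm_features, glszm_features, gldm_features, ngtdm_features):
            f1, f2 = fn(d1), fn(d2)
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], abs=1e-10), (fn.__name__, k)
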