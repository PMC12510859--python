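"""Normalization, discretization, texture features and delta features."""

import numpy as np
import pytest

from deltazone import (
    FeatureConfig,
    FeatureVector,
    delta_features,
    discretize,
    extract_features,
    znormalize,
)
from deltazone import radiomics as R
from conftest import make_mask, make_volume
from oracles import texture_features_brute


def _roi_all(shape=(4, 4, 4)):
    return make_mask(np.ones(shape))


class TestZnormalize:
    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            znormalize(make_volume(np.full((4, 4, 4), 3.0)), _roi_all())

    def test_reference_mean_zero_sd_one(self, rng):
        vol = make_volume(rng.normal(100, 30, (6, 6, 6)))
        ref = make_mask(rng.random((6, 6, 6)) < 0.5)
        out = znormalize(vol, ref)
        assert out.data[ref.data].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.data[ref.data].std() == pytest.approx(1.0, abs=1e-9)

    def test_positive_affine_invariance(self, rng):
        vol = make_volume(rng.normal(0, 10, (5, 5, 5)))
        ref = _roi_all((5, 5, 5))
        scaled = make_volume(3.7 * vol.data - 42.0)
        assert np.allclose(znormalize(vol, ref).data, znormalize(scaled, ref).data,
                           atol=1e-9)


class TestDiscretize:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.0, 10.0, 24.9], [1, 1, 1]), ([0.0, 25.0, 50.0], [1, 2, 3])],
    )
    def test_worked_examples(self, values, expected):
        arr = np.zeros((3, 1, 1))
        arr[:, 0, 0] = values
        mask = make_mask(np.ones((3, 1, 1)))
        lv = discretize(make_volume(arr), mask, 25.0)
        assert list(lv[:, 0, 0]) == expected

    def test_matches_loop_oracle(self, rng):
        arr = rng.uniform(-300, 500, (5, 5, 4))
        mask = make_mask(rng.random((5, 5, 4)) < 0.7)
        lv = discretize(make_volume(arr), mask, 25.0)
        lo = arr[mask.data].min()
        for idx in zip(*np.nonzero(mask.data)):
            assert lv[idx] == int(np.floor((arr[idx] - lo) / 25.0)) + 1
        assert (lv[~mask.data] == 0).all()


class TestTextureOracle:
    """Vectorized matrix features must equal brute-force enumeration on
    small ROIs to 1e-9."""

    def _compare(self, levels):
        n_vox = int((levels > 0).sum())
        ng = int(levels.max())
        imp = {}
        per = []
        for d in R.DIRECTIONS_3D:
            P = R.glcm_matrix(levels, d, ng)
            if P.sum() > 0:
                per.append(R.glcm_features(P))
        imp.update(R._mean_over_directions(per))
        imp.update(R._mean_over_directions(
            [R.glrlm_features(R.glrlm_matrix(levels, d, ng), n_vox)
             for d in R.DIRECTIONS_3D]))
        imp.update(R.glszm_features(R.glszm_matrix(levels, ng), n_vox))
        imp.update(R.ngtdm_features(*R.ngtdm_table(levels, ng)))
        imp.update(R.gldm_features(R.gldm_matrix(levels, ng), n_vox))
        ref = texture_features_brute(levels, n_vox)
        assert set(imp) == set(ref)
        for k in ref:
            assert imp[k] == pytest.approx(ref[k], abs=1e-9), k

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_small_rois(self, seed):
        rng = np.random.default_rng(seed)
        levels = np.zeros((4, 4, 4), dtype=np.int64)
        mask = rng.random((4, 4, 4)) < 0.75
        levels[mask] = rng.integers(1, 6, int(mask.sum()))
        if not (levels > 0).any():
            pytest.skip("empty draw")
        self._compare(levels)

    def test_hand_case_2x2x1(self):
        levels = np.array([[[1], [2]], [[3], [4]]], dtype=np.int64)
        self._compare(levels)
        # hand-enumerated co-occurrence for direction (1,0,0):
        # pairs (1,3) and (2,4), symmetrized
        P = R.glcm_matrix(levels, (1, 0, 0), 4)
        expect = np.zeros((4, 4))
        expect[0, 2] = expect[2, 0] = 1
        expect[1, 3] = expect[3, 1] = 1
        assert np.array_equal(P, expect)
        # runs along (1,0,0): four runs of length 1
        Rm = R.glrlm_matrix(levels, (1, 0, 0), 4)
        assert Rm.shape == (4, 1) and Rm.sum() == 4

    def test_checkerboard_ngtdm_contrast_closed_form(self):
        # 3x3x1 checkerboard of levels {1,2}: every voxel's neighbours are
        # all the opposite level mixed with same-level diagonals; compute the
        # defining sums directly
        levels = np.indices((3, 3, 1)).sum(axis=0) % 2 + 1
        levels = levels.astype(np.int64)
        n_i, s_i = R.ngtdm_table(levels, 2)
        ref_n, ref_s = [0.0, 0.0], [0.0, 0.0]
        for i in range(3):
            for j in range(3):
                g = levels[i, j, 0]
                nbrs = [
                    levels[a, b, 0]
                    for a in range(max(0, i - 1), min(3, i + 2))
                    for b in range(max(0, j - 1), min(3, j + 2))
                    if (a, b) != (i, j)
                ]
                ref_n[g - 1] += 1
                ref_s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
        assert np.allclose(n_i, ref_n) and np.allclose(s_i, ref_s)
        feats = R.ngtdm_features(n_i, s_i)
        ngp, nvp = 2, 9
        p = np.asarray(ref_n) / nvp
        expected_contrast = (p[0] * p[1] * 1.0 * 2) / (ngp * (ngp - 1)) * sum(ref_s) / nvp
        assert feats["ngtdm_Contrast"] == pytest.approx(expected_contrast, abs=1e-12)


class TestExtractFeatures:
    def test_uniform_roi_entropy_and_contrast_zero(self):
        vol = make_volume(np.full((3, 3, 3), 5.0))
        fv = extract_features(vol, _roi_all((3, 3, 3)),
                              FeatureConfig(classes=("firstorder", "glcm")))
        assert fv["firstorder_Entropy"] == 0.0
        assert fv["glcm_Contrast"] == 0.0
        assert fv.degenerate

    def test_every_feature_finite_on_noise(self, rng):
        vol = make_volume(rng.normal(0, 50, (6, 6, 5)))
        mask = make_mask(rng.random((6, 6, 5)) < 0.8)
        fv = extract_features(vol, mask)
        assert len(fv) > 100
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_enumeration_order_invariance(self, rng):
        """Features depend only on the voxel set, not memory layout."""
        arr = rng.normal(0, 30, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        fv1 = extract_features(make_volume(arr), make_mask(mask))
        fv2 = extract_features(
            make_volume(np.asfortranarray(arr).copy()), make_mask(mask.copy())
        )
        for k in fv1.values:
            assert fv1[k] == pytest.approx(fv2[k], rel=1e-12)

    def test_small_roi_rejected_for_texture(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="2 voxels"):
            extract_features(vol, make_mask(mask))

    def test_shape_features_on_cube(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:6, 2:6, 2:6] = True  # 4x4x4 cube at 1 mm
        fv = extract_features(make_volume(np.random.default_rng(0).normal(size=(8, 8, 8))),
                              make_mask(m), FeatureConfig(classes=("shape",)))
        assert fv["shape_VoxelVolume"] == pytest.approx(64.0)
        assert fv["shape_SurfaceArea"] == pytest.approx(6 * 16.0)
        assert fv["shape_Maximum3DDiameter"] == pytest.approx(3 * np.sqrt(3))
        assert fv["shape_Elongation"] == pytest.approx(1.0)


class TestDeltaFeatures:
    def _fv(self, d, **kw):
        return FeatureVector(values=d, **kw)

    def test_identical_timepoints_give_zero(self):
        fv = self._fv({"glcm_Contrast": 2.0, "firstorder_Mean": -4.0})
        out = delta_features(fv, fv)
        assert all(v == 0.0 for v in out.values.values())

    def test_formula(self):
        out = delta_features(self._fv({"a_b": 2.0}), self._fv({"a_b": 3.0}))
        assert out.values["a_b"] == pytest.approx(50.0)

    def test_zero_baseline_flagged_undefined_not_zeroed(self):
        out = delta_features(self._fv({"a_b": 0.0, "c_d": 1.0}),
                             self._fv({"a_b": 5.0, "c_d": 2.0}))
        assert out.undefined == ("a_b",)
        assert "a_b" not in out.values
        assert out.values["c_d"] == pytest.approx(100.0)

    def test_mismatched_names_rejected(self):
        with pytest.raises(ValueError, match="name sets"):
            delta_features(self._fv({"a_b": 1.0}), self._fv({"x_y": 1.0}))

    def test_affine_rescaling_of_both_scans_cancels(self, rng):
        """Post-normalization delta features are unchanged when both CTs
        undergo the same positive affine intensity map."""
        arr1 = rng.normal(0, 30, (6, 6, 6))
        arr2 = arr1 + rng.normal(0, 10, (6, 6, 6))
        ref = _roi_all((6, 6, 6))
        roi = make_mask(rng.random((6, 6, 6)) < 0.6)
        cfg = FeatureConfig(classes=("firstorder", "glcm"), bin_width=0.25)

        def pipeline(a1, a2):
            n1 = znormalize(make_volume(a1), ref)
            n2 = znormalize(make_volume(a2), ref)
            f1 = extract_features(n1, roi, cfg)
            f2 = extract_features(n2, roi, cfg)
            return delta_features(f1, f2)

        base = pipeline(arr1, arr2)
        scaled = pipeline(2.5 * arr1 + 100.0, 2.5 * arr2 + 100.0)
        assert base.undefined == scaled.undefined
        for k in base.values:
            assert base.values[k] == pytest.approx(scaled.values[k], rel=1e-9, abs=1e-9)
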