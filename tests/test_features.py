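"""Radiomic features: oracle equivalence, invariances, the 215 contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import focusradiomics as fr
from focusradiomics.features import (GLCM_NAMES, GLRLM_NAMES, QuantizedROI,
                                     crop_to_bbox, direction_set_3d,
                                     extract_case, feature_names,
                                     glcm_matrix, glcm_stats, glrlm_stats,
                                     intensity_features, quantize,
                                     shape_features)
from conftest import random_quantized_roi
from oracles import glcm_stats_bruteforce, glrlm_stats_bruteforce


def ball_mask(radius_vox, shape):
    c = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    return r2 <= radius_vox ** 2


class TestCrop:
    def test_single_voxel_margin_zero(self, one_case):
        mask = np.zeros_like(one_case.mask.data)
        mask[8, 10, 12] = True
        series, cropped = crop_to_bbox(one_case.series,
                                       fr.LesionMask(mask, (1, 1, 1)), 0)
        assert cropped.data.shape == (1, 1, 1)
        assert series.data.shape == (5, 1, 1, 1)

    def test_huge_margin_is_full_volume(self, one_case):
        series, cropped = crop_to_bbox(one_case.series, one_case.mask, 1000)
        assert cropped.data.shape == one_case.mask.data.shape

    def test_empty_mask_raises(self, one_case):
        empty = fr.LesionMask(np.zeros_like(one_case.mask.data), (1, 1, 1))
        with pytest.raises(ValueError):
            crop_to_bbox(one_case.series, empty, 0)

    def test_features_invariant_to_cropping(self, one_case):
        direct = extract_case(one_case.series, one_case.mask, margin=0)
        series, mask = crop_to_bbox(one_case.series, one_case.mask, 3)
        after = extract_case(series, mask, margin=0)
        pd.testing.assert_series_equal(direct, after)


class TestQuantize:
    def test_constant_roi_maps_to_level_one(self):
        vol = np.full((3, 3, 3), 7.0)
        q = quantize(vol, np.ones((3, 3, 3), bool), 32)
        assert set(q.levels[q.mask]) == {1}

    def test_boundary_rule(self):
        vol = np.arange(256, dtype=float).reshape(4, 8, 8)
        q = quantize(vol, np.ones((4, 8, 8), bool), 32)
        assert q.levels[0, 0, 0] == 1
        assert q.levels[3, 7, 7] == 32

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(0)
        vol = rng.random((5, 5, 5)) * 100
        mask = rng.random((5, 5, 5)) < 0.6
        mask[0, 0, 0] = True
        q = quantize(vol, mask, 8)
        vals = vol[mask]
        mn, mx = vals.min(), vals.max()
        for v, lev in zip(vals, q.levels[mask]):
            expect = min(int(np.floor((v - mn) / (mx - mn) * 8)) + 1, 8)
            assert lev == expect

    @given(n_levels=st.integers(2, 64))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_levels_always_in_range(self, n_levels):
        rng = np.random.default_rng(n_levels)
        vol = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        q = quantize(vol, mask, n_levels)
        assert q.levels[mask].min() >= 1
        assert q.levels[mask].max() <= n_levels


class TestIntensity:
    def test_constant_roi(self):
        vol = np.full((2, 3, 4), 5.0)
        f = intensity_features(vol, np.ones((2, 3, 4), bool), (1, 2, 0.5))
        assert f["Max"] == f["Min"] == f["Mean"] == 5.0
        assert f["Sigma"] == f["Variance"] == 0.0
        assert f["IntegratedIntensity"] == pytest.approx(5.0 * 24 * 1.0)

    def test_two_voxel_closed_form(self):
        vol = np.array([[[0.0, 2.0]]])
        f = intensity_features(vol, np.ones((1, 1, 2), bool), (1, 1, 1))
        assert f["Mean"] == 1.0
        assert f["Variance"] == 1.0
        assert f["Sigma"] == 1.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(10, 4, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.5
        mask[2, 2, 2] = True
        spacing = (1.0, 0.5, 0.5)
        f = intensity_features(vol, mask, spacing)
        vals = [vol[z, y, x] for z in range(6) for y in range(6)
                for x in range(6) if mask[z, y, x]]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        assert f["Mean"] == pytest.approx(mean, rel=1e-10)
        assert f["Variance"] == pytest.approx(var, rel=1e-10)
        assert f["Max"] == max(vals) and f["Min"] == min(vals)
        assert f["IntegratedIntensity"] == pytest.approx(
            sum(vals) * 0.25, rel=1e-10)


class TestShape:
    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((5, 5, 5), bool)
        mask.flat[:10] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["Volume"] == pytest.approx(10.0)

    def test_sphere_is_round(self):
        mask = ball_mask(6.0, (15, 15, 15))
        f = shape_features(mask, (1, 1, 1))
        assert f["Eccentricity"] == pytest.approx(0.0, abs=0.1)
        assert f["Elongation"] == pytest.approx(1.0, abs=0.1)

    def test_prolate_ellipsoid_elongation(self):
        # 2:1 prolate ellipsoid: semi-axes 8, 4, 4 voxels
        shape = (21, 21, 21)
        c = 10.0
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        mask = (((zz - c) / 8.0) ** 2 + ((yy - c) / 4.0) ** 2
                + ((xx - c) / 4.0) ** 2) <= 1.0
        f = shape_features(mask, (1, 1, 1))
        assert f["Elongation"] == pytest.approx(2.0, rel=0.1)
        assert f["MajorAxisLength"] / f["MinorAxisLength"] == pytest.approx(
            2.0, rel=0.15)

    def test_single_voxel_warns_and_zeroes(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.warns(UserWarning):
            f = shape_features(mask, (1, 1, 1))
        assert f["Eccentricity"] == 0.0 and f["MajorAxisLength"] == 0.0


class TestDirections:
    def test_thirteen_unique_directions(self):
        dirs = direction_set_3d()
        assert len(dirs) == 13
        assert {(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)} <= set(dirs)
        for d in dirs:
            assert tuple(-x for x in d) not in dirs


class TestGLCM:
    def test_constant_roi_single_cell(self):
        q = quantize(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool), 16)
        s = glcm_stats(q, (0, 0, 1))
        assert s["Energy"] == 1.0
        assert s["Entropy"] == 0.0
        assert s["InverseDifferenceMoment"] == 1.0
        assert s["Inertia"] == 0.0

    def test_line_roi_exhaustive_pairs(self):
        levels = np.array([[[1, 2, 1, 2]]], dtype=np.int64)
        q = QuantizedROI(levels, 2, np.ones((1, 1, 4), bool), (1, 1, 1))
        p = glcm_matrix(q, (0, 0, 1))
        # pairs (1,2),(2,1),(1,2) symmetrised: 6 entries, all off-diagonal
        assert p[0, 0] == 0 and p[1, 1] == 0
        assert p[0, 1] == pytest.approx(0.5) and p[1, 0] == pytest.approx(0.5)
        s = glcm_stats(q, (0, 0, 1))
        ref = glcm_stats_bruteforce(levels, q.mask, (0, 0, 1), 2)
        for k in s:
            assert s[k] == pytest.approx(ref[k], rel=1e-12)

    def test_no_valid_pair_returns_none(self):
        q = quantize(np.ones((1, 1, 1)), np.ones((1, 1, 1), bool), 4)
        assert glcm_stats(q, (0, 0, 1)) is None

    def test_probability_identities_random_rois(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            q = random_quantized_roi(rng)
            for d in [(0, 0, 1), (1, 1, 0)]:
                s = glcm_stats(q, d)
                if s is None:
                    continue
                assert s["Entropy"] >= 0
                assert 0 < s["Energy"] <= 1


class TestGLRLM:
    def test_alternating_levels_all_unit_runs(self):
        levels = np.array([[[1, 2, 1, 2, 1]]], dtype=np.int64)
        q = QuantizedROI(levels, 2, np.ones((1, 1, 5), bool), (1, 1, 1))
        s = glrlm_stats(q, (0, 0, 1))
        assert s["ShortRunEmphasis"] == 1.0
        assert s["LongRunEmphasis"] == 1.0

    def test_constant_line_single_run(self):
        L = 6
        levels = np.full((1, 1, L), 3, dtype=np.int64)
        q = QuantizedROI(levels, 4, np.ones((1, 1, L), bool), (1, 1, 1))
        s = glrlm_stats(q, (0, 0, 1))
        assert s["LongRunEmphasis"] == pytest.approx(L ** 2)

    def test_runs_break_at_mask_boundaries(self):
        levels = np.full((1, 1, 5), 2, dtype=np.int64)
        mask = np.array([[[True, True, False, True, True]]])
        levels[~mask] = 0
        q = QuantizedROI(levels, 2, mask, (1, 1, 1))
        ref = glrlm_stats_bruteforce(levels, mask, (0, 0, 1), 2)
        s = glrlm_stats(q, (0, 0, 1))
        # two runs of length 2, never one of length 4
        assert s["LongRunEmphasis"] == pytest.approx(4.0)
        assert s["LongRunEmphasis"] == pytest.approx(ref["LongRunEmphasis"])

    def test_matches_bruteforce_on_random_roi(self):
        rng = np.random.default_rng(21)
        q = random_quantized_roi(rng, max_side=4, n_levels=3)
        for d in direction_set_3d():
            s = glrlm_stats(q, d)
            ref = glrlm_stats_bruteforce(q.levels, q.mask, d, q.n_levels)
            assert (s is None) == (ref is None)
            if s is not None:
                for k in s:
                    assert s[k] == pytest.approx(ref[k], rel=1e-10)


class TestExtractCase:
    def test_215_features_43_per_timepoint(self, one_case):
        vec = extract_case(one_case.series, one_case.mask)
        assert len(vec) == 215
        for t in range(5):
            assert sum(name.endswith(f"_T{t}") for name in vec.index) == 43
        assert np.isfinite(vec.to_numpy()).all()

    def test_shape_block_identical_across_timepoints(self, one_case):
        vec = extract_case(one_case.series, one_case.mask)
        for name in ("Eccentricity", "Elongation", "Volume"):
            vals = {vec[f"{name}_T{t}"] for t in range(5)}
            assert len(vals) == 1

    def test_enhancement_visible_in_mean(self):
        cfg = fr.CohortConfig(n_benign=1, n_malignant=1, noise_sigma=0.0,
                              seed=2)
        case = fr.generate_case(fr.MALIGNANT, cfg, np.random.default_rng(6))
        vec = extract_case(case.series, case.mask)
        assert vec["Mean_T0"] < vec["Mean_T2"]

    def test_deterministic(self, one_case):
        a = extract_case(one_case.series, one_case.mask)
        b = extract_case(one_case.series, one_case.mask)
        pd.testing.assert_series_equal(a, b)

    def test_intensity_shift_covariance(self, one_case):
        vec = extract_case(one_case.series, one_case.mask)
        shifted = fr.DynamicSeries(one_case.series.data + 25.0,
                                   one_case.series.spacing)
        vec2 = extract_case(shifted, one_case.mask)
        for t in range(5):
            assert vec2[f"Mean_T{t}"] == pytest.approx(
                vec[f"Mean_T{t}"] + 25.0, rel=1e-9)
            assert vec2[f"Sigma_T{t}"] == pytest.approx(
                vec[f"Sigma_T{t}"], rel=1e-9)
            # min-max binning absorbs the shift: texture unchanged
            assert vec2[f"Entropy_mean_T{t}"] == pytest.approx(
                vec[f"Entropy_mean_T{t}"], rel=1e-9)
            assert vec2[f"ShortRunEmphasis_mean_T{t}"] == pytest.approx(
                vec[f"ShortRunEmphasis_mean_T{t}"], rel=1e-9)

    def test_rotation_coherence_of_direction_means(self):
        # rotating the ROI by 90 deg permutes the 13 directions, so the
        # mean-over-directions GLCM statistics are unchanged
        rng = np.random.default_rng(17)
        vol = rng.random((6, 6, 6))
        mask = ball_mask(2.6, (6, 6, 6))
        rot_vol = np.rot90(vol, k=1, axes=(1, 2))
        rot_mask = np.rot90(mask, k=1, axes=(1, 2))
        from focusradiomics.features import _aggregate_directions
        q1 = quantize(vol, mask, 8)
        q2 = quantize(rot_vol, rot_mask, 8)
        a = _aggregate_directions(glcm_stats, q1, GLCM_NAMES)
        b = _aggregate_directions(glcm_stats, q2, GLCM_NAMES)
        for name in GLCM_NAMES:
            assert a[f"{name}_mean"] == pytest.approx(b[f"{name}_mean"],
                                                      rel=1e-9)

    def test_cohort_table_layout(self, feature_table):
        assert feature_table.shape == (6, 216)
        assert feature_table.index.name == "case_id"
        assert list(feature_table.columns[:-1]) == feature_names()
        assert set(feature_table["label"]) == {fr.BENIGN, fr.MALIGNANT}
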