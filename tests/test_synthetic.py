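"""Synthetic DCE-MRI generator: kinetics, geometry, determinism, motion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import focusradiomics as fr
from focusradiomics.affine import Affine2D


class TestKineticCurve:
    def test_persistent_curve_is_monotone(self):
        p = fr.KineticParams(100.0, 0.9, 1.2, 0.0)
        e = fr.kinetic_curve(p)
        assert e[0] == 0.0
        assert np.all(np.diff(e) >= 0)

    def test_zero_amplitude_is_flat(self):
        p = fr.KineticParams(100.0, 0.0, 2.0, 0.5)
        assert np.allclose(fr.kinetic_curve(p), 0.0)

    def test_washout_peaks_before_last_timepoint(self):
        # closed form evaluated on a dense grid locates the peak inside
        # the acquisition window; the sampled curve must reflect it
        p = fr.KineticParams(100.0, 1.0, 3.0, 0.4)
        t = np.linspace(0, 4, 4001)
        dense = p.wash_in_amplitude * (1 - np.exp(-3.0 * t)) * np.exp(-0.4 * t)
        assert t[np.argmax(dense)] < 4.0
        e = fr.kinetic_curve(p)
        assert e[4] < e.max()
        assert np.argmax(e) < 4

    @given(amp=st.floats(0.1, 3.0), kin=st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_no_washout_never_decreases(self, amp, kin):
        e = fr.kinetic_curve(fr.KineticParams(50.0, amp, kin, 0.0))
        assert np.all(np.diff(e) >= -1e-12)

    @pytest.mark.parametrize("bad", [
        dict(baseline_intensity=0.0, wash_in_amplitude=1, wash_in_rate=1),
        dict(baseline_intensity=10, wash_in_amplitude=-0.1, wash_in_rate=1),
        dict(baseline_intensity=10, wash_in_amplitude=1, wash_in_rate=-1),
        dict(baseline_intensity=10, wash_in_amplitude=1, wash_in_rate=1,
             time_points=(0, 1, 1, 3, 4)),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            fr.KineticParams(**bad)


class TestGenerateCase:
    def test_noiseless_masked_mean_matches_curve(self):
        cfg = fr.CohortConfig(n_benign=1, n_malignant=1, noise_sigma=0.0,
                              texture_heterogeneity=0.0, seed=5)
        case = fr.generate_case(fr.MALIGNANT, cfg, np.random.default_rng(2))
        kin = case.truth["kinetics"]
        curve = fr.kinetic_curve(kin)
        for t in range(5):
            mean = case.series.data[t][case.mask.data].mean()
            assert mean == pytest.approx(
                kin.baseline_intensity * (1 + curve[t]), rel=1e-12)

    def test_textured_noiseless_mean_still_exact(self):
        # the texture field has exactly zero mean inside the mask
        cfg = fr.CohortConfig(n_benign=1, n_malignant=1, noise_sigma=0.0,
                              texture_heterogeneity=0.3, seed=5)
        case = fr.generate_case(fr.BENIGN, cfg, np.random.default_rng(4))
        kin = case.truth["kinetics"]
        curve = fr.kinetic_curve(kin)
        mean = case.series.data[3][case.mask.data].mean()
        assert mean == pytest.approx(kin.baseline_intensity * (1 + curve[3]),
                                     rel=1e-10)

    def test_fixed_seed_reproduces_case_exactly(self, small_cfg):
        a = fr.generate_case(fr.BENIGN, small_cfg, np.random.default_rng(9))
        b = fr.generate_case(fr.BENIGN, small_cfg, np.random.default_rng(9))
        assert np.array_equal(a.series.data, b.series.data)
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_mask_single_connected_component(self, small_cohort):
        from scipy import ndimage
        for case in small_cohort:
            _, n = ndimage.label(case.mask.data)
            assert n == 1

    def test_digitized_ball_volume_close_to_analytic(self):
        # 5 mm sphere at 1 mm spacing: voxel count vs (pi/6) d1 d2 d3
        cfg = fr.CohortConfig(n_benign=1, n_malignant=1,
                              lesion_diameter_range=(5.0, 5.0), seed=0)
        for s in range(5):
            case = fr.generate_case(fr.BENIGN, cfg, np.random.default_rng(s))
            semi = np.asarray(case.truth["semi_axes_mm"])
            analytic = 4.0 / 3.0 * np.pi * semi.prod()
            voxels = case.mask.data.sum() * 1.0
            # digitisation error of a ~65-voxel ball stays well under 30%
            assert abs(voxels - analytic) / analytic < 0.3

    def test_lesion_too_large_raises(self):
        cfg = fr.CohortConfig(n_benign=1, n_malignant=1,
                              volume_shape=(6, 6, 6),
                              lesion_diameter_range=(10.0, 10.0))
        with pytest.raises(ValueError, match="fit"):
            fr.generate_case(fr.BENIGN, cfg, np.random.default_rng(0))


class TestCohort:
    def test_counts_and_labels(self, small_cohort):
        labels = [c.label for c in small_cohort]
        assert len(small_cohort) == 6
        assert labels.count(fr.BENIGN) == 3
        assert labels.count(fr.MALIGNANT) == 3

    def test_same_seed_identical_cohort(self, small_cfg, small_cohort):
        again = fr.generate_cohort(small_cfg)
        for a, b in zip(small_cohort, again):
            assert np.array_equal(a.series.data, b.series.data)

    def test_motionless_truth_is_identity(self, small_cohort):
        for case in small_cohort:
            for per_t in case.truth["motion"]:
                assert all(a.is_identity() for a in per_t)


class TestInjectMotion:
    def test_zero_amplitude_is_noop(self, one_case):
        moved = fr.inject_motion(one_case, 0.0, np.random.default_rng(1))
        assert moved is one_case

    def test_fixed_seed_reproducible_transforms(self, one_case):
        a = fr.inject_motion(one_case, 2.0, np.random.default_rng(7))
        b = fr.inject_motion(one_case, 2.0, np.random.default_rng(7))
        for ta, tb in zip(a.truth["motion"], b.truth["motion"]):
            for x, y in zip(ta, tb):
                assert np.allclose(x.matrix, y.matrix)
                assert np.allclose(x.translation, y.translation)

    def test_t0_untouched_and_inverse_restores(self, one_case):
        moved = fr.inject_motion(one_case, 2.0, np.random.default_rng(3))
        assert np.array_equal(moved.series.data[0], one_case.series.data[0])
        inv = [[a.inverse() for a in per_t] for per_t in moved.truth["motion"]]
        restored = fr.synthetic.apply_slice_transforms(moved.series, inv)
        core = (slice(None), slice(4, -4), slice(4, -4))
        for t in range(1, 5):
            diff = np.abs(restored.data[t][core[1:]]
                          - one_case.series.data[t][core[1:]])
            # double bilinear resampling: small interpolation error only
            assert np.median(diff) < 1.0


class TestPersistence:
    def test_nifti_roundtrip(self, one_case, tmp_path):
        fr.save_case(one_case, tmp_path)
        back = fr.load_case(tmp_path / one_case.case_id)
        assert back.label == one_case.label
        assert back.series.spacing == one_case.series.spacing
        assert np.allclose(back.series.data, one_case.series.data,
                           atol=1e-4)   # float32 storage
        assert np.array_equal(back.mask.data, one_case.mask.data)
        kin = back.truth["kinetics"]
        assert kin.wash_in_rate == pytest.approx(
            one_case.truth["kinetics"].wash_in_rate)


class TestPlantedTable:
    def test_shapes_and_effect_size(self):
        df = fr.planted_feature_table(n_per_class=40, n_informative=2,
                                      n_noise=10, effect_size=2.0, seed=1)
        assert df.shape == (80, 13)
        mal = df[df.label == fr.MALIGNANT]
        ben = df[df.label == fr.BENIGN]
        shift = mal["info_00"].mean() - ben["info_00"].mean()
        assert shift == pytest.approx(2.0, abs=0.7)
        null_shift = mal["noise_00"].mean() - ben["noise_00"].mean()
        assert abs(null_shift) < 0.7
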