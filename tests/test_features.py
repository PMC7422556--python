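"""Windowing, the calibration-segment rule, and the 26-feature vector."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoehar import labels as L
from shoehar.features import (
    FEATURE_NAMES,
    build_feature_set,
    compute_feature_matrix,
    compute_features,
    extract_calibration_segment,
    segment_windows,
)
from shoehar.signal_io import AccelRecording, AnnotationLog, Interval

from oracles import oracle_features

FIDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "n, expected",
        [(4900, 48), (200, 1), (199, 0), (300, 2), (399, 2), (400, 3)],
    )
    def test_window_count_closed_form(self, n, expected):
        windows, starts = segment_windows(np.zeros((n, 3)), fs=100.0)
        assert len(windows) == expected
        if expected:
            assert windows.shape[1:] == (200, 3)
            assert starts[1] - starts[0] == 100 if expected > 1 else True

    @given(n=st.integers(min_value=0, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_count_formula_property(self, n):
        windows, _ = segment_windows(np.zeros((n, 3)), fs=100.0)
        length, stride = 200, 100
        expected = 0 if n < length else (n - length) // stride + 1
        assert len(windows) == expected

    def test_windows_are_contiguous_slices(self, rng):
        x = rng.normal(size=(450, 3))
        windows, starts = segment_windows(x, fs=100.0)
        for w, s in zip(windows, starts):
            np.testing.assert_array_equal(w, x[s : s + 200])


class TestCalibrationSegment:
    def test_240s_interval(self):
        log = AnnotationLog("s", [Interval(0, 240, "sitting")])
        seg = extract_calibration_segment(log)
        assert seg.intervals[0].start == pytest.approx(186.0)
        assert seg.intervals[0].end == pytest.approx(235.0)

    def test_60s_interval_keeps_6th_to_55th_second(self):
        log = AnnotationLog("s", [Interval(0, 60, "kneeling")])
        seg = extract_calibration_segment(log)
        assert (seg.intervals[0].start, seg.intervals[0].end) == (6.0, 55.0)

    def test_short_interval_names_activity(self):
        log = AnnotationLog("s", [Interval(0, 59, "walking")])
        with pytest.raises(ValueError, match="walking"):
            extract_calibration_segment(log)

    def test_segment_is_49s_for_any_interval(self):
        log = AnnotationLog(
            "s", [Interval(10, 100, "sitting"), Interval(100, 333, "standing")]
        )
        for iv in extract_calibration_segment(log).intervals:
            assert iv.end - iv.start == pytest.approx(49.0)


class TestComputeFeatures:
    def test_constant_gravity_closed_form(self):
        w = np.tile([0.0, 0.0, 1.0], (200, 1))
        f = compute_features(w, fs=100.0)
        assert f[FIDX["mean_x"]] == 0 and f[FIDX["mean_y"]] == 0
        assert f[FIDX["mean_z"]] == pytest.approx(1.0)
        for n in ("std_x", "std_y", "std_z", "mag_std", "mag_range", "mag_iqr"):
            assert f[FIDX[n]] == 0
        for n in ("corr_xy", "corr_xz", "corr_yz"):
            assert f[FIDX[n]] == 0  # zero-variance convention
        assert f[FIDX["mag_mean"]] == pytest.approx(1.0)
        assert f[FIDX["sma"]] == pytest.approx(1.0)
        assert f[FIDX["tilt_mean_deg"]] == pytest.approx(0.0)
        for n in ("domfreq_x", "domfreq_y", "domfreq_z", "mag_domfreq"):
            assert f[FIDX[n]] == 0
        assert f[FIDX["mag_spec_entropy"]] == 0
        assert np.all(np.isfinite(f))

    def test_pure_sinusoid_dominant_frequency(self):
        fs, dur = 100.0, 2.0
        t = np.arange(int(fs * dur)) / fs
        w = np.column_stack(
            [np.zeros_like(t), np.zeros_like(t), 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)]
        )
        f = compute_features(w, fs)
        assert f[FIDX["domfreq_z"]] == pytest.approx(2.0)
        assert f[FIDX["mag_domfreq"]] == pytest.approx(2.0)

    def test_moment_features_permutation_invariant(self, rng):
        w = rng.normal(0, 0.5, (200, 3))
        f_fwd = compute_features(w, 100.0)
        f_rev = compute_features(w[::-1], 100.0)
        for n in (
            "mean_x", "mean_y", "mean_z", "std_x", "std_y", "std_z",
            "mag_mean", "mag_std", "mag_range", "mag_iqr",
            "mag_skewness", "mag_kurtosis", "sma", "tilt_mean_deg",
        ):
            assert f_fwd[FIDX[n]] == pytest.approx(f_rev[FIDX[n]], abs=1e-12)

    def test_scaling_property(self, rng):
        w = rng.normal(0, 0.5, (100, 3)) + [0, 0, 1]
        c = 2.5
        f1 = compute_features(w, 100.0)
        f2 = compute_features(c * w, 100.0)
        scaled = ("mean_x", "mean_y", "mean_z", "std_x", "std_y", "std_z",
                  "mag_mean", "mag_std", "mag_range", "mag_iqr", "sma")
        for n in scaled:
            assert f2[FIDX[n]] == pytest.approx(c * f1[FIDX[n]], rel=1e-9)
        for n in ("corr_xy", "corr_xz", "corr_yz", "tilt_mean_deg",
                  "mag_skewness", "mag_kurtosis", "mag_mcr",
                  "domfreq_x", "domfreq_y", "domfreq_z", "mag_domfreq",
                  "mag_spec_entropy"):
            assert f2[FIDX[n]] == pytest.approx(f1[FIDX[n]], rel=1e-9, abs=1e-12)

    def test_nonfinite_input_raises(self):
        w = np.zeros((10, 3))
        w[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_features(w, 100.0)

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Implementation matches direct-definition sums and O(L^2) DFT."""
        for _ in range(25):
            w = rng.normal(0, 1, (64, 3))
            got = compute_features(w, 100.0)
            want = oracle_features(w.tolist(), 100.0)
            np.testing.assert_allclose(got, want, atol=1e-9, rtol=0)

    def test_batch_matches_single(self, rng):
        windows = rng.normal(0, 1, (7, 64, 3))
        batch = compute_feature_matrix(windows, 100.0)
        for k in range(7):
            np.testing.assert_allclose(
                batch[k], compute_features(windows[k], 100.0), atol=1e-12
            )


def _recording(n, fs=100.0, value=(0.0, 0.0, 1.0)):
    return AccelRecording("s1", np.tile(value, (n, 1)), fs=fs)


class TestBuildFeatureSet:
    def test_lab_mode_60s_sitting(self):
        rec = _recording(6000)
        log = AnnotationLog("s1", [Interval(0, 60, "sitting")])
        fs = build_feature_set(rec, log, "lab")
        assert len(fs) == 48
        assert (fs.frame["label"] == "sitting").all()

    def test_lab_mode_maps_walking_speeds(self, rng):
        rec = AccelRecording("s1", rng.normal(0, 0.1, (12000, 3)))
        log = AnnotationLog(
            "s1", [Interval(0, 60, "walking_slow"), Interval(60, 120, "walking_brisk")]
        )
        fs = build_feature_set(rec, log, "lab")
        assert set(fs.frame["label"]) == {"walking"}
        assert len(fs) == 96

    def test_freeliving_mode_full_coverage(self):
        rec = _recording(12000)
        log = AnnotationLog(
            "s1", [Interval(0, 120, "walking", source="observer")]
        )
        fs = build_feature_set(rec, log, "free_living")
        assert len(fs) == 119  # floor((12000-200)/100)+1
        assert (fs.frame["label"] == "walking").all()
        assert (fs.frame["label_purity"] == 1.0).all()

    def test_freeliving_no_annotations_empty(self):
        rec = _recording(12000)
        fs = build_feature_set(rec, AnnotationLog("s1", []), "free_living")
        assert len(fs) == 0

    def test_freeliving_majority_vote_and_purity(self):
        rec = _recording(400)
        # window [1, 3): 1.5 s walking vs 0.5 s sitting -> walking, purity .75
        log = AnnotationLog(
            "s1",
            [
                Interval(0, 2.5, "walking", source="observer"),
                Interval(2.5, 4.0, "sitting", source="observer"),
            ],
        )
        fs = build_feature_set(rec, log, "free_living")
        row = fs.frame[fs.frame["t_start"] == 1.0].iloc[0]
        assert row["label"] == "walking"
        assert row["label_purity"] == pytest.approx(0.75)

    def test_freeliving_tie_goes_to_earlier_interval(self):
        rec = _recording(400)
        log = AnnotationLog(
            "s1",
            [
                Interval(0, 2.0, "sitting", source="observer"),
                Interval(2.0, 4.0, "standing", source="observer"),
            ],
        )
        fs = build_feature_set(rec, log, "free_living")
        row = fs.frame[fs.frame["t_start"] == 1.0].iloc[0]
        assert row["label"] == "sitting"
        assert row["label_purity"] == pytest.approx(0.5)

    def test_features_depend_only_on_samples_not_clock(self):
        rec_a = _recording(6000)
        rec_b = AccelRecording("s1", rec_a.samples, fs=100.0, start_time=1000.0)
        log_a = AnnotationLog("s1", [Interval(0, 60, "sitting")])
        log_b = AnnotationLog("s1", [Interval(1000, 1060, "sitting")])
        fa = build_feature_set(rec_a, log_a, "lab")
        fb = build_feature_set(rec_b, log_b, "lab")
        np.testing.assert_allclose(fa.X, fb.X, atol=1e-12)

    def test_csv_roundtrip(self, tmp_path, small_lab_features):
        p = tmp_path / "features.csv"
        sub = small_lab_features.subset(small_lab_features.subjects == "lab00")
        sub.to_csv(p)
        from shoehar.features import FeatureSet

        back = FeatureSet.from_csv(p)
        assert back.feature_names == sub.feature_names
        np.testing.assert_allclose(back.X, sub.X, rtol=1e-12)
        assert list(back.frame["label"]) == list(sub.frame["label"])
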