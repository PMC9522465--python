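"""Duplicate-frame detection: change statistic, thresholding, rates, evenness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vidqc
from vidqc.duplicates import TooShortError


class TestGrayscale:
    def test_white_maps_to_white(self):
        px = np.full((2, 2, 3), 255, dtype=np.uint8)
        assert np.all(vidqc.grayscale(px) == 255)

    def test_gray_passthrough_identity(self, rng):
        f = rng.integers(0, 256, (6, 7), dtype=np.uint8)
        assert vidqc.grayscale(f) is f

    def test_pure_red_luma(self):
        px = np.zeros((1, 1, 3), dtype=np.uint8)
        px[0, 0] = (255, 0, 0)
        assert vidqc.grayscale(px)[0, 0] == 76  # 0.299 * 255 = 76.245

    def test_bad_channel_count_rejected(self):
        with pytest.raises(ValueError):
            vidqc.grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestMaxChangeSeries:
    def test_identical_frames_give_zero(self):
        f = np.full((2, 8, 8), 100, dtype=np.uint8)
        s = vidqc.max_change_series(vidqc.FrameStream(f, 30))
        assert s.tolist() == [0]

    def test_single_pixel_change(self):
        f = np.full((2, 8, 8), 100, dtype=np.uint8)
        f[1, 3, 4] += 5
        assert vidqc.max_change_series(vidqc.FrameStream(f, 30)).tolist() == [5]

    def test_matches_exhaustive_oracle(self, rng):
        f = rng.integers(0, 256, (10, 8, 8), dtype=np.uint8)
        series = vidqc.max_change_series(vidqc.FrameStream(f, 30))
        for i in range(9):
            brute = max(
                abs(int(f[i + 1, r, c]) - int(f[i, r, c]))
                for r in range(8) for c in range(8)
            )
            assert series[i] == brute

    def test_no_wraparound_at_extremes(self):
        f = np.zeros((2, 4, 4), dtype=np.uint8)
        f[1] = 255
        assert vidqc.max_change_series(vidqc.FrameStream(f, 30)).tolist() == [255]

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            vidqc.max_change_series(vidqc.FrameStream(np.zeros((1, 4, 4), np.uint8), 30))


class TestSelectThreshold:
    def test_presets_by_lighting(self):
        ch = np.arange(40)
        assert vidqc.select_threshold(ch, "red", "preset").threshold == 8
        assert vidqc.select_threshold(ch, "white", "preset").threshold == 10

    def test_bimodal_two_regime_series(self, rng):
        ch = np.concatenate(
            [rng.integers(0, 4, 500), rng.integers(22, 29, 500)]
        )
        res = vidqc.select_threshold(ch, mode="auto")
        assert res.bimodal
        assert 3 < res.threshold < 22
        assert res.mode_low < res.threshold < res.mode_high

    def test_one_point_distribution_is_unimodal(self):
        res = vidqc.select_threshold(np.full(300, 12), mode="auto")
        assert not res.bimodal
        assert res.threshold is None

    def test_broad_single_mode_is_unimodal(self, rng):
        ch = np.clip(rng.normal(30, 4, 2000).round(), 0, 255).astype(int)
        res = vidqc.select_threshold(ch, mode="auto")
        assert not res.bimodal


class TestClassification:
    def test_boundary_is_inclusive(self):
        mask = vidqc.classify_duplicates(np.array([8, 9, 0]), 8)
        assert mask.tolist() == [True, False, True]

    def test_threshold_zero_flags_bit_identical_pair(self):
        assert vidqc.classify_duplicates(np.array([0]), 0).tolist() == [True]

    def test_threshold_255_flags_everything(self, rng):
        ch = rng.integers(0, 256, 50)
        assert vidqc.classify_duplicates(ch, 255).all()

    @given(st.integers(0, 254))
    @settings(derandomize=True, deadline=None)
    def test_count_monotone_in_threshold(self, thr):
        ch = np.arange(256)
        lo = vidqc.classify_duplicates(ch, thr).sum()
        hi = vidqc.classify_duplicates(ch, thr + 1).sum()
        assert lo <= hi


class TestEvenness:
    def test_equal_counts_give_zero(self):
        # one duplicate per minute across 5 minutes
        mask = np.zeros(300 * 30 - 1, dtype=bool)
        mask[[100, 2000, 4000, 6000, 8000]] = True
        assert vidqc.duplicate_evenness(mask, 300.0, fps=30.0) == pytest.approx(0.0)

    def test_clustered_counts_hand_value(self):
        # 100 duplicates all inside the first of 5 bins: counts [100,0,0,0,0]
        mask = np.zeros(9000 - 1, dtype=bool)
        mask[np.arange(100, 200)] = True
        vmr = vidqc.duplicate_evenness(mask, 300.0, fps=30.0)
        assert vmr == pytest.approx(1600.0 / 20.0)

    def test_empty_mask_is_zero(self):
        assert vidqc.duplicate_evenness(np.zeros(100, bool), 300.0, 30.0) == 0.0

    def test_short_recording_returns_zero(self):
        assert vidqc.duplicate_evenness(np.ones(10, bool), 30.0, 1.0) == 0.0


class TestAnalyzeDuplicates:
    def test_recovers_injected_duplicates_exactly(self, short_session):
        spec, stream, manifest = short_session
        meta = vidqc.RecordingMeta(spec.nominal_fps, "red")
        report = vidqc.analyze_duplicates(stream, meta, 8)
        assert report.total_duplicates == len(manifest.duplicate_positions)
        assert set(np.flatnonzero(report.duplicate_mask) + 1) == set(
            manifest.duplicate_positions
        )

    def test_duplicate_free_stream_reports_zero(self, clean_session):
        spec, stream, _ = clean_session
        report = vidqc.analyze_duplicates(stream, vidqc.RecordingMeta(30), 8)
        assert report.total_duplicates == 0
        assert report.duplicates_per_min == 0.0
        assert report.true_fps == pytest.approx(spec.nominal_fps)

    def test_rate_and_true_fps_equations(self, short_session):
        spec, stream, manifest = short_session
        report = vidqc.analyze_duplicates(stream, vidqc.RecordingMeta(30), 8)
        length = len(stream) / spec.nominal_fps
        d = report.total_duplicates
        assert report.duplicates_per_min == pytest.approx(d / length * 60.0)
        assert report.true_fps == pytest.approx((len(stream) - d) / length)
        assert report.true_fps <= len(stream) / length

    def test_unimodal_auto_reports_no_duplicates_not_zero(self):
        spec = vidqc.SessionSpec(
            duration_s=10.0, trajectory=vidqc.Stationary(), noise_sigma=0.5, seed=3
        )
        stream, _ = vidqc.render_session(spec)
        report = vidqc.analyze_duplicates(stream, vidqc.RecordingMeta(30), "auto")
        assert report.unimodal_flag
        assert report.total_duplicates is None
        assert report.duplicates_per_min is None

    def test_timestamp_table_overrides_length_convention(self, short_session):
        spec, stream, _ = short_session
        table, _ = vidqc.make_timestamp_fixture(len(stream), 40.0, 30.0)
        report = vidqc.analyze_duplicates(
            stream, vidqc.RecordingMeta(30), 8, timestamps=table
        )
        assert report.recording_length_s == pytest.approx(40.0)

    def test_noise_robust_recovery_over_seeds(self):
        """Re-noised duplicates (motionless re-captures at sigma = 0.5) stay far
        below the red-light threshold while motion steps stay far above it, so
        injected counts are recovered exactly across seeds."""
        for seed in range(5):
            spec = vidqc.SessionSpec(
                duration_s=10.0, noise_sigma=0.5, n_duplicates=40,
                renoise_duplicates=True, seed=seed,
            )
            stream, manifest = vidqc.render_session(spec)
            report = vidqc.analyze_duplicates(stream, vidqc.RecordingMeta(30, "red"), 8)
            assert report.total_duplicates == len(manifest.duplicate_positions)
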