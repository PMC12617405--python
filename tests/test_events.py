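import dataclasses
import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from actimetry.benchmark import match_events
from actimetry.events import (
    DetectedEvent,
    EventDetectionParams,
    blur_stack,
    detect_events,
    event_threshold,
    events_per_filament,
    ratio_stack,
    temporal_max_projection,
)
from actimetry.io import MovieStack
from actimetry.segmentation import SegmentationParams, background_stats
from actimetry.simulate import GlidingSimConfig, simulate_gliding_movie
from actimetry.tracking import Track, TrackPoint, TrackingParams, link_tracks
from actimetry.segmentation import measure_filaments, segment_frame

PX, DT = 0.108, 1.0


def _movie(frames):
    return MovieStack(np.asarray(frames, dtype=float), PX, DT)


def _detach_movie():
    """One stationary filament that detaches at frame 11 (seed chosen for that)."""
    cfg = GlidingSimConfig(n_filaments=1, motile_fraction=0.0, wobble_rate_per_s=0.0,
                           detach_rate_per_s=0.05, n_frames=20, image_shape=(96, 96),
                           length_sd_um=0.0, length_mean_um=2.0, seed=2)
    movie, truth = simulate_gliding_movie(cfg)
    assert [(e.kind, e.frame) for e in truth.events] == [("detach", 11)]
    return movie, truth


def _wobble_movie():
    """One stationary filament that wobbles once at frame 12."""
    cfg = GlidingSimConfig(n_filaments=1, motile_fraction=0.0, wobble_rate_per_s=0.02,
                           detach_rate_per_s=0.0, n_frames=20, image_shape=(96, 96),
                           length_sd_um=0.0, length_mean_um=2.0, seed=2)
    movie, truth = simulate_gliding_movie(cfg)
    assert [(e.kind, e.frame) for e in truth.events] == [("wobble", 12)]
    return movie, truth


class TestBlur:
    def test_constant_frame_unchanged(self):
        movie = _movie(np.full((3, 16, 16), 9.0))
        out = blur_stack(movie, 2.0)
        np.testing.assert_allclose(out.frames, 9.0)

    def test_impulse_normalization(self):
        frames = np.zeros((2, 33, 33))
        frames[:, 16, 16] = 1.0
        out = blur_stack(_movie(frames), 2.0)
        assert out.frames[0].sum() == pytest.approx(1.0, abs=1e-6)
        assert out.frames[0, 16, 16] == out.frames[0].max()

    def test_matches_dense_convolution_oracle(self, rng):
        """Brute-force separable-kernel convolution with symmetric padding."""
        sigma = 2.0
        frame = rng.uniform(0, 100, size=(32, 32))
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(frame, radius, mode="symmetric")
        expected = np.empty_like(frame)
        for i in range(32):
            for j in range(32):
                expected[i, j] = np.sum(padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel)
        out = blur_stack(_movie(frame[None].repeat(2, axis=0)), sigma)
        np.testing.assert_allclose(out.frames[0], expected, atol=1e-6)


class TestRatioStack:
    def test_identical_frames_ratio_one(self):
        movie = _movie(np.full((4, 16, 16), 50.0))
        rs = ratio_stack(movie)
        np.testing.assert_allclose(rs.ratios, 1.0, atol=1e-9)

    def test_appearing_object_peak_ratio(self):
        """An object appearing at 4x background gives a peak ratio near 4."""
        bg = 100.0
        frame0 = np.full((64, 64), bg)
        blob = np.zeros((64, 64))
        blob[25:39, 25:39] = 3 * bg  # flat top wide enough to survive the blur
        frames = np.stack([frame0, frame0 + gaussian_filter(blob, 1.0)])
        rs = ratio_stack(_movie(frames), EventDetectionParams(epsilon=0.0))
        assert rs.ratios.max() == pytest.approx(4.0, rel=0.05)

    def test_time_reversal_inverts_ratios(self, rng):
        frames = rng.uniform(50, 150, size=(5, 16, 16))
        params = EventDetectionParams(epsilon=0.0)
        fwd = ratio_stack(_movie(frames), params).ratios
        rev = ratio_stack(_movie(frames[::-1]), params).ratios
        np.testing.assert_allclose(rev, 1.0 / fwd[::-1], rtol=1e-9)


class TestThreshold:
    @pytest.mark.parametrize(
        "mean,sd,k,expected",
        [(100.0, 5.0, 4.0, 1.2), (100.0, 0.0, 4.0, 1.0), (50.0, 5.0, 4.0, 1.4)],
    )
    def test_formula(self, mean, sd, k, expected):
        assert event_threshold(mean, sd, k) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            event_threshold(0.0, 5.0, 4.0)


class TestDetection:
    def test_identical_frames_no_events(self):
        movie = _movie(np.full((5, 32, 32), 80.0))
        rs = ratio_stack(movie)
        assert detect_events(rs, 1.2) == []

    def test_single_detachment_detected_at_vacated_position(self):
        movie, truth = _detach_movie()
        params = EventDetectionParams(two_sided=True)
        mean, sd = background_stats(movie, SegmentationParams())
        thr = event_threshold(mean, sd, params.threshold_k)
        events = detect_events(ratio_stack(movie, params), thr, params)
        assert len(events) == 1
        (ev,) = events
        true = truth.events[0]
        assert ev.frame in (true.frame - 1, true.frame)
        assert math.hypot(ev.row - true.row, ev.col - true.col) <= 3.0

    def test_one_sided_default_sees_wobble_not_detach(self):
        """Brightening-only detection catches the reappearing side only."""
        movie, _ = _detach_movie()
        params = EventDetectionParams()  # one-sided
        mean, sd = background_stats(movie, SegmentationParams())
        thr = event_threshold(mean, sd, params.threshold_k)
        assert detect_events(ratio_stack(movie, params), thr, params) == []

        movie, truth = _wobble_movie()
        mean, sd = background_stats(movie, SegmentationParams())
        thr = event_threshold(mean, sd, params.threshold_k)
        events = detect_events(ratio_stack(movie, params), thr, params)
        tm, _ = match_events(events, truth, tol_px=5.0)
        assert tm == 1

    def test_increasing_k_never_adds_events(self):
        cfg = GlidingSimConfig(n_filaments=8, motile_fraction=0.0,
                               wobble_rate_per_s=0.05, detach_rate_per_s=0.02,
                               n_frames=30, min_separation_um=1.0, seed=3)
        movie, _ = simulate_gliding_movie(cfg)
        params = EventDetectionParams(two_sided=True)
        mean, sd = background_stats(movie, SegmentationParams())
        rs = ratio_stack(movie, params)
        counts = [
            len(detect_events(rs, event_threshold(mean, sd, k), params))
            for k in (2.0, 3.0, 4.0, 6.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_scale_invariance_of_event_pipeline(self):
        movie, _ = _wobble_movie()
        params = EventDetectionParams(two_sided=True, epsilon=0.0)

        def run(stack):
            mean, sd = background_stats(stack, SegmentationParams())
            thr = event_threshold(mean, sd, params.threshold_k)
            evs = detect_events(ratio_stack(stack, params), thr, params)
            return [(e.frame, round(e.row, 6), round(e.col, 6), e.area_px) for e in evs]

        scaled = movie.with_frames(movie.frames * 7.5)
        assert run(movie) == run(scaled)
        rs1 = ratio_stack(movie, params)
        rs2 = ratio_stack(scaled, params)
        np.testing.assert_allclose(rs1.ratios, rs2.ratios, rtol=1e-12)


class TestMaxProjection:
    def test_identical_movie_projection_at_unity(self, tmp_path):
        movie = _movie(np.full((4, 16, 16), 40.0))
        rs = ratio_stack(movie)
        png = tmp_path / "proj.png"
        proj = temporal_max_projection(rs, png_path=png)
        np.testing.assert_allclose(proj, 1.0, atol=1e-9)
        assert png.exists()

    def test_projection_dominates_every_ratio_frame(self):
        movie, _ = _wobble_movie()
        rs = ratio_stack(movie)
        proj = temporal_max_projection(rs)
        assert (proj >= rs.ratios - 1e-12).all()

    def test_wobble_marks_old_and_new_positions(self):
        """Brightening projection marks the new position; the inverted-ratio
        projection marks the vacated one."""
        movie, truth = _wobble_movie()
        params = EventDetectionParams(two_sided=True)
        mean, sd = background_stats(movie, SegmentationParams())
        thr = event_threshold(mean, sd, params.threshold_k)
        rs = ratio_stack(movie, params)
        proj_bright = temporal_max_projection(rs)
        proj_dark = (1.0 / rs.ratios).max(axis=0)
        ev = truth.events[0]
        new = (int(round(ev.row)), int(round(ev.col)))
        old = (int(round(ev.row_alt)), int(round(ev.col_alt)))
        assert proj_bright[new] > thr
        assert proj_dark[old] > thr


class TestEventsPerFilament:
    def _track_at(self, tid, row, col, n=10):
        return Track(tid, [TrackPoint(t, row, col, 1.0) for t in range(n)], PX)

    def test_zero_events_zero_frequency(self):
        _, freq, unassigned = events_per_filament([], [self._track_at(0, 5, 5)], 2.0, PX)
        assert freq == 0.0 and unassigned == 0

    def test_far_event_unassigned(self):
        ev = DetectedEvent(frame=3, row=80.0, col=80.0, area_px=5, peak_ratio=1.5)
        out, freq, unassigned = events_per_filament([ev], [self._track_at(0, 5, 5)], 2.0, PX)
        assert out[0].track_id is None
        assert unassigned == 1 and freq == 0.0

    def test_near_event_assigned_to_nearest_track(self):
        ev = DetectedEvent(frame=3, row=6.0, col=5.0, area_px=5, peak_ratio=1.5)
        tracks = [self._track_at(0, 5, 5), self._track_at(1, 50, 50)]
        out, freq, unassigned = events_per_filament([ev], tracks, 2.0, PX)
        assert out[0].track_id == 0
        assert freq == 0.5 and unassigned == 0

    def test_wobble_frequency_matches_poisson_rate(self):
        """Mean one-sided events per filament ~ rate x duration (3-SE bound)."""
        rate = 0.03
        cfg = GlidingSimConfig(n_filaments=12, motile_fraction=0.0,
                               wobble_rate_per_s=rate, detach_rate_per_s=0.0,
                               min_separation_um=1.2, seed=17)
        movie, truth = simulate_gliding_movie(cfg)
        params = EventDetectionParams()  # one-sided: one spot per wobble
        seg = SegmentationParams()
        mean, sd = background_stats(movie, seg)
        thr = event_threshold(mean, sd, params.threshold_k)
        events = detect_events(ratio_stack(movie, params), thr, params)
        measures = []
        for t in range(movie.n_frames):
            lf = segment_frame(movie.frames[t], seg)
            measures += measure_filaments(lf, PX, frame=t)
        tracks = link_tracks(measures, TrackingParams(), PX)
        _, freq, _ = events_per_filament(events, tracks, 2.0, PX)
        lam = rate * movie.duration_s
        se = math.sqrt(lam / cfg.n_filaments)
        assert abs(freq - lam) <= 3 * se
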