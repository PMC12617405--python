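import dataclasses

import numpy as np
import pytest
from scipy import stats

from actimetry.ringtiming import segment_phases
from actimetry.simulate import (
    CELL_PRESETS,
    RING_PRESETS,
    GlidingSimConfig,
    ParameterError,
    RingSimConfig,
    simulate_cells,
    simulate_gliding_movie,
    simulate_ring_traces,
)


class TestGlidingMovie:
    def test_pure_background_statistics(self):
        cfg = GlidingSimConfig(n_filaments=0, n_frames=10, seed=0)
        movie, truth = simulate_gliding_movie(cfg)
        assert truth.events == []
        assert abs(movie.frames.mean() - cfg.background_mean) < 0.01 * cfg.background_mean
        assert abs(movie.frames.std() - cfg.background_sd) < 0.05 * cfg.background_sd

    def test_static_config_constant_signal(self, static_gliding_config):
        movie, truth = simulate_gliding_movie(static_gliding_config)
        assert truth.events == []
        # noiseless signal identical in every frame
        for t in range(1, movie.n_frames):
            np.testing.assert_array_equal(truth.signal[t], truth.signal[0])

    def test_seed_determinism(self, static_gliding_config):
        cfg = dataclasses.replace(static_gliding_config, wobble_rate_per_s=0.05,
                                  detach_rate_per_s=0.02, motile_fraction=0.5)
        m1, t1 = simulate_gliding_movie(cfg)
        m2, t2 = simulate_gliding_movie(cfg)
        np.testing.assert_array_equal(m1.frames, m2.frames)
        assert [(e.frame, e.kind, e.row) for e in t1.events] == [
            (e.frame, e.kind, e.row) for e in t2.events
        ]

    def test_detach_terminates_trajectory_and_event_frames_in_range(self):
        cfg = GlidingSimConfig(n_filaments=10, detach_rate_per_s=0.05,
                               wobble_rate_per_s=0.05, n_frames=30, seed=7)
        _, truth = simulate_gliding_movie(cfg)
        assert truth.events, "expected at least one event at these rates"
        for ev in truth.events:
            assert 1 <= ev.frame <= cfg.n_frames - 1
            if ev.kind == "detach":
                fil = truth.filaments[ev.filament_id]
                assert not fil.present[ev.frame :].any()
                assert fil.present[: ev.frame].all()

    def test_filament_longer_than_field_rejected(self):
        with pytest.raises(ParameterError, match="field of view"):
            GlidingSimConfig(length_mean_um=20.0, image_shape=(64, 64))

    def test_invalid_motile_fraction_rejected(self):
        with pytest.raises(ParameterError):
            GlidingSimConfig(motile_fraction=1.5)

    def test_translation_conserves_integrated_intensity(self):
        """A gliding filament's rendered mass stays constant while in-field."""
        cfg = GlidingSimConfig(
            n_filaments=1, motile_fraction=1.0, wobble_rate_per_s=0.0,
            detach_rate_per_s=0.0, n_frames=20, length_sd_um=0.0, seed=3,
        )
        movie, truth = simulate_gliding_movie(cfg)
        sums = truth.signal.reshape(cfg.n_frames, -1).sum(axis=1)
        assert sums.std() / sums.mean() < 0.01

    def test_wobble_counts_follow_poisson_rates(self):
        """Chi-square GOF of per-filament wobble counts vs the Poisson law."""
        rate, n_frames = 0.03, 60
        counts = []
        for seed in range(10):
            cfg = GlidingSimConfig(
                n_filaments=20, motile_fraction=0.0, wobble_rate_per_s=rate,
                detach_rate_per_s=0.0, n_frames=n_frames,
                image_shape=(96, 96), length_mean_um=2.0, length_sd_um=0.5,
                seed=100 + seed,
            )
            _, truth = simulate_gliding_movie(cfg)
            per_fil = np.zeros(cfg.n_filaments, dtype=int)
            for ev in truth.events:
                per_fil[ev.filament_id] += 1
            counts.extend(per_fil)
        counts = np.asarray(counts)
        assert counts.size == 200
        lam = rate * (n_frames - 1) * 1.0
        kmax = 4
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = np.array(
            [stats.poisson.pmf(k, lam) for k in range(kmax)]
            + [stats.poisson.sf(kmax - 1, lam)]
        ) * counts.size
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01


class TestCellCohorts:
    def test_mean_length_within_clt_bound(self):
        p = CELL_PRESETS["MEEE"]
        cells = simulate_cells(n=1000, seed=7, **p)
        lengths = np.array([c.length_um for c in cells])
        se = p["length_sd_um"] / np.sqrt(1000)
        assert abs(lengths.mean() - p["length_mean_um"]) < 3 * se
        assert all(c.length_um > c.width_um > 0 for c in cells)

    def test_degenerate_cohort_identical(self):
        cells = simulate_cells(5, 10.0, 0.0, 4.0, 0.0, seed=1)
        assert len({(c.length_um, c.width_um) for c in cells}) == 1

    def test_reproducible_given_seed(self):
        a = simulate_cells(10, 12.0, 1.0, 4.0, 0.3, seed=9)
        b = simulate_cells(10, 12.0, 1.0, 4.0, 0.3, seed=9)
        assert [(c.length_um, c.width_um) for c in a] == [
            (c.length_um, c.width_um) for c in b
        ]

    def test_negative_sd_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cells(10, 12.0, -1.0, 4.0, 0.3)


class TestRingTraces:
    def test_trace_grid_arithmetic(self):
        cfg = RingSimConfig(
            coalescence_mean_min=21.0, coalescence_sd_min=0.0,
            dwell_mean_min=6.0, dwell_sd_min=0.0,
            constriction_mean_min=45.0, constriction_sd_min=0.0,
            diameter_sd_um=0.0, n_cells=1, seed=0,
        )
        (trace, truth), = simulate_ring_traces(cfg)
        assert trace.times_min.size == 72 // 3 + 1
        assert truth.total_min == 72.0
        # diameter strictly decreasing across constriction samples
        con = [
            d for t, s, d in zip(trace.times_min, trace.states, trace.diameters_um)
            if s == "ring" and t >= 27.0
        ]
        assert all(a > b for a, b in zip(con, con[1:]))

    def test_generating_durations_are_grid_multiples(self):
        for trace, truth in simulate_ring_traces(RING_PRESETS["MEEE"]):
            for v in (truth.coalescence_min, truth.dwell_min, truth.constriction_min):
                assert v > 0 and v % trace.frame_interval_min == 0

    def test_mean_coalescence_within_clt_bound(self):
        cfg = dataclasses.replace(RING_PRESETS["REE"], n_cells=25, seed=3)
        truths = [t for _, t in simulate_ring_traces(cfg)]
        mean = np.mean([t.coalescence_min for t in truths])
        se = cfg.coalescence_sd_min / np.sqrt(cfg.n_cells)
        assert abs(mean - cfg.coalescence_mean_min) < 3 * se

    def test_traces_are_segmentable(self):
        for trace, _ in simulate_ring_traces(RING_PRESETS["REE"]):
            segment_phases(trace)  # no censoring, no malformed traces
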