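"""Nearest-neighbor filament tracking and motility summaries.

Per-frame filament measures are linked frame-to-frame by greedy globally
nearest-pair assignment — at the low filament densities of gliding assays
this matches global assignment while staying deterministic and auditable.
A track is called "moving" only if both its mean frame-to-frame speed and
its net displacement clear configurable thresholds, which excludes
stationary filaments whose centroids jitter with noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import numpy as np

from .segmentation import FilamentMeasure

__all__ = [
    "TrackingParams",
    "TrackPoint",
    "Track",
    "MotilitySummary",
    "link_tracks",
    "track_speed",
    "net_displacement_um",
    "classify_moving",
    "summarize_motility",
]


@dataclass(frozen=True)
class TrackingParams:
    """Linking and motility-classification thresholds.

    max_disp_um
        Maximum centroid displacement per frame for linking (scaled by the
        number of elapsed frames when bridging gaps).
    max_gap
        Frames a track may go unmatched before it is closed.
    min_track_len
        Minimum number of points for a track to be reported.
    moving_speed_threshold_um_per_s, moving_net_disp_um
        Both must be exceeded for a track to count as moving.
    """

    max_disp_um: float = 2.0
    max_gap: int = 2
    min_track_len: int = 3
    moving_speed_threshold_um_per_s: float = 0.05
    moving_net_disp_um: float = 0.5

    def __post_init__(self) -> None:
        if not self.max_disp_um > 0:
            raise ValueError("max_disp_um must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_track_len < 1:
            raise ValueError("min_track_len must be >= 1")
        if self.moving_speed_threshold_um_per_s < 0 or self.moving_net_disp_um < 0:
            raise ValueError("moving thresholds must be >= 0")


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    row: float  # px
    col: float  # px
    length_um: float


@dataclass
class Track:
    """One filament's linked trajectory (centroids in pixels)."""

    track_id: int
    points: list[TrackPoint]
    pixel_size_um: float

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points])

    @property
    def centroids_px(self) -> np.ndarray:
        return np.array([[p.row, p.col] for p in self.points])

    def duration_s(self, frame_interval_s: float) -> float:
        return (self.points[-1].frame - self.points[0].frame) * frame_interval_s


def net_displacement_um(track: Track) -> float:
    """Straight-line distance between first and last centroid."""
    a, b = track.points[0], track.points[-1]
    return math.hypot(b.row - a.row, b.col - a.col) * track.pixel_size_um


def track_speed(track: Track, frame_interval_s: float) -> float:
    """Mean frame-to-frame speed, μm/s.

    Averages centroid displacement over consecutive point pairs divided by
    the actual elapsed time (gap steps use the real time span).
    """
    if len(track.points) < 2:
        raise ValueError(f"track {track.track_id}: speed undefined for < 2 points")
    speeds = []
    for a, b in zip(track.points, track.points[1:]):
        dist_um = math.hypot(b.row - a.row, b.col - a.col) * track.pixel_size_um
        elapsed = (b.frame - a.frame) * frame_interval_s
        speeds.append(dist_um / elapsed)
    return float(np.mean(speeds))


def classify_moving(track: Track, params: TrackingParams, frame_interval_s: float) -> bool:
    """Moving iff mean speed AND net displacement both exceed their thresholds."""
    if len(track.points) < 2:
        return False
    return (
        track_speed(track, frame_interval_s) > params.moving_speed_threshold_um_per_s
        and net_displacement_um(track) > params.moving_net_disp_um
    )


def link_tracks(
    measures: Iterable[FilamentMeasure],
    params: TrackingParams,
    pixel_size_um: float,
) -> list[Track]:
    """Link per-frame measures into tracks.

    Greedy globally nearest-pair assignment between open track heads and
    the next frame's measures, among pairs within ``max_disp_um`` times the
    elapsed frame count; unmatched measures open new tracks; tracks
    unmatched for more than ``max_gap`` frames are closed. Deterministic:
    distance ties break toward the lower track id, then lower label.
    """
    by_frame: dict[int, list[FilamentMeasure]] = {}
    for m in measures:
        by_frame.setdefault(m.frame, []).append(m)
    if not by_frame:
        return []
    for frame_measures in by_frame.values():
        frame_measures.sort(key=lambda m: m.filament_label)

    open_tracks: list[Track] = []
    closed: list[Track] = []
    next_id = 0
    for f in range(min(by_frame), max(by_frame) + 1):
        ms = by_frame.get(f, [])
        # candidate links (distance, track order, label order)
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = tr.points[-1]
            gap = f - last.frame
            if gap < 1:
                continue
            limit_px = params.max_disp_um * gap / pixel_size_um
            for mi, m in enumerate(ms):
                d = math.hypot(m.centroid_row - last.row, m.centroid_col - last.col)
                if d <= limit_px:
                    pairs.append((d, tr.track_id, m.filament_label, ti, mi))
        pairs.sort()
        used_t: set[int] = set()
        used_m: set[int] = set()
        for d, _tid, _lab, ti, mi in pairs:
            if ti in used_t or mi in used_m:
                continue
            used_t.add(ti)
            used_m.add(mi)
            m = ms[mi]
            open_tracks[ti].points.append(
                TrackPoint(f, m.centroid_row, m.centroid_col, m.length_um)
            )
        for mi, m in enumerate(ms):
            if mi not in used_m:
                open_tracks.append(
                    Track(
                        track_id=next_id,
                        points=[TrackPoint(f, m.centroid_row, m.centroid_col, m.length_um)],
                        pixel_size_um=pixel_size_um,
                    )
                )
                next_id += 1
        still_open = []
        for tr in open_tracks:
            if f - tr.points[-1].frame > params.max_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
    closed.extend(open_tracks)
    kept = [t for t in closed if len(t.points) >= params.min_track_len]
    kept.sort(key=lambda t: t.track_id)
    return kept


@dataclass(frozen=True)
class MotilitySummary:
    """Movie-level motility metrics.

    ``n_filaments`` is the mean per-frame segmented filament count
    (rounded); ``n_tracks`` the number of reported tracks — both are
    emitted because "filaments per movie" can mean either. Percent moving
    and mean moving speed are NaN when no tracks exist;
    ``events_per_filament`` is filled in by the event-detection stage.
    """

    movie_id: str
    n_filaments: int
    n_tracks: int
    percent_moving: float
    mean_speed_moving_um_per_s: float
    events_per_filament: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_tracks and not (0 <= self.percent_moving <= 100):
            raise ValueError("percent_moving must be within [0, 100]")


def summarize_motility(
    tracks: Sequence[Track],
    params: TrackingParams,
    frame_interval_s: float,
    movie_id: str = "movie",
    mean_frame_count: float | None = None,
    events_per_filament: float = float("nan"),
) -> MotilitySummary:
    """One summary per movie.

    ``percent_moving`` = 100 x moving tracks / all tracks; the mean speed
    averages moving tracks only. With zero tracks the percentage and speed
    fields are NaN (explicit not-available markers).
    """
    n_tracks = len(tracks)
    n_filaments = int(round(mean_frame_count)) if mean_frame_count is not None else n_tracks
    if n_tracks == 0:
        return MotilitySummary(movie_id, n_filaments, 0, float("nan"), float("nan"))
    moving = [t for t in tracks if classify_moving(t, params, frame_interval_s)]
    percent = 100.0 * len(moving) / n_tracks
    mean_speed = (
        float(np.mean([track_speed(t, frame_interval_s) for t in moving]))
        if moving
        else 0.0
    )
    return MotilitySummary(
        movie_id=movie_id,
        n_filaments=n_filaments,
        n_tracks=n_tracks,
        percent_moving=percent,
        mean_speed_moving_um_per_s=mean_speed,
        events_per_filament=events_per_filament,
    )
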