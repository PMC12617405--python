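"""Detachment/wobbling detection via thresholded frame-ratio stacks.

The core change detector of the pipeline: each frame is Gaussian-blurred,
consecutive frames are divided pixel-wise — ratio frame i is
(blurred frame i+1) / (blurred frame i) — and pixels whose ratio exceeds

    threshold = 1 + k * (background SD / background mean)        (k = 4)

mark locations that brightened far beyond what background fluctuation
allows. Supra-threshold connected components become candidate spots;
adjacent-frame spots at the same location are merged so one physical event
is counted once. A filament abruptly displaced sideways ("wobbling")
brightens at its new position; a filament leaving the surface
("detachment") darkens at the old one, which the optional two-sided mode
catches by also thresholding the inverted ratio. The temporal maximum
projection of the ratio stack, displayed on a fixed linear scale, gives
the standard one-glance rendering of where events occurred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as _cc_label, regionprops

from .io import MovieStack
from .tracking import Track

__all__ = [
    "EventDetectionParams",
    "RatioStack",
    "DetectedEvent",
    "blur_stack",
    "ratio_stack",
    "event_threshold",
    "detect_events",
    "temporal_max_projection",
    "events_per_filament",
]


@dataclass(frozen=True)
class EventDetectionParams:
    """Event-detector knobs.

    blur_radius_px
        Gaussian blur applied before the ratio; interpreted as the Gaussian
        sigma (the common imaging-software reading of "blur radius").
    threshold_k
        Multiplier k in the cutoff 1 + k * (background SD / mean).
    min_spot_area_px
        Smallest supra-threshold component accepted as a spot.
    merge_radius_px, merge_frames
        Spots in ratio frames at most ``merge_frames`` apart with centroids
        within ``merge_radius_px`` are one event (earliest frame kept).
    two_sided
        Also threshold the inverted ratio, catching pure disappearances
        (detachment without reappearance). Default off: the published
        pipeline displays and thresholds brightening only.
    display_lo, display_hi
        Linear display range for the max-projection rendering.
    epsilon
        Denominator guard added to both blurred frames; ``None`` means
        1e-6 times the movie median.
    """

    blur_radius_px: float = 2.0
    threshold_k: float = 4.0
    min_spot_area_px: int = 4
    merge_radius_px: float = 5.0
    merge_frames: int = 1
    two_sided: bool = False
    display_lo: float = 1.3
    display_hi: float = 3.0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not self.blur_radius_px > 0:
            raise ValueError("blur_radius_px must be > 0")
        if not self.threshold_k > 0:
            raise ValueError("threshold_k must be > 0")
        if self.min_spot_area_px < 1:
            raise ValueError("min_spot_area_px must be >= 1")
        if not self.display_lo < self.display_hi:
            raise ValueError("display_lo must be < display_hi")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class RatioStack:
    """(T-1, H, W) stack of per-pixel frame ratios plus source calibration."""

    ratios: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    @property
    def n_ratio_frames(self) -> int:
        return self.ratios.shape[0]


@dataclass(frozen=True)
class DetectedEvent:
    """One detachment/wobbling candidate.

    ``frame`` is the ratio-frame index: the event occurred between source
    frames ``frame`` and ``frame + 1``. ``peak_ratio`` is the largest
    (possibly inverted, for darkening spots) ratio inside the spot.
    ``kind`` is ``"unclassified"`` — wobbling and detachment are pooled.
    """

    frame: int
    row: float
    col: float
    area_px: int
    peak_ratio: float
    polarity: str = "bright"  # "bright" | "dark"
    kind: str = "unclassified"
    track_id: int | None = None


def blur_stack(stack: MovieStack, radius_px: float) -> MovieStack:
    """Per-frame 2-D Gaussian smoothing (sigma = radius_px, reflective edges)."""
    if not radius_px > 0:
        raise ValueError("radius_px must be > 0")
    blurred = gaussian_filter(
        np.asarray(stack.frames, dtype=float), sigma=(0.0, radius_px, radius_px),
        mode="reflect",
    )
    return stack.with_frames(blurred)


def ratio_stack(stack: MovieStack, params: EventDetectionParams | None = None) -> RatioStack:
    """Blur and divide consecutive frames: ratio[i] = blurred[i+1]/blurred[i]."""
    params = params or EventDetectionParams()
    if stack.n_frames < 2:
        raise ValueError("ratio analysis needs >= 2 frames")
    blurred = blur_stack(stack, params.blur_radius_px).frames
    eps = params.epsilon
    if eps is None:
        eps = 1e-6 * float(np.median(stack.frames))
    ratios = (blurred[1:] + eps) / (blurred[:-1] + eps)
    bad = ~np.isfinite(ratios)
    if bad.any():
        frame = int(np.argwhere(bad)[0, 0])
        raise FloatingPointError(f"non-finite ratio at ratio-frame {frame}")
    return RatioStack(ratios, stack.pixel_size_um, stack.frame_interval_s)


def event_threshold(background_mean: float, background_sd: float, threshold_k: float = 4.0) -> float:
    """Background-derived ratio cutoff: 1 + k * (SD / mean).

    A pixel ratio above this is unlikely under pure background fluctuation
    of the given relative noise.
    """
    if not background_mean > 0:
        raise ValueError("background_mean must be > 0")
    if background_sd < 0:
        raise ValueError("background_sd must be >= 0")
    return 1.0 + threshold_k * (background_sd / background_mean)


def _frame_spots(
    ratio_frame: np.ndarray, threshold: float, min_area: int, two_sided: bool
) -> list[tuple[float, float, int, float, str]]:
    """Supra-threshold spots of one ratio frame: (row, col, area, peak, polarity)."""
    spots = []
    masks = [(ratio_frame > threshold, ratio_frame, "bright")]
    if two_sided:
        with np.errstate(divide="ignore"):
            inv = 1.0 / ratio_frame
        masks.append((inv > threshold, inv, "dark"))
    for mask, values, polarity in masks:
        labels, n = _cc_label(mask, connectivity=2, return_num=True)
        for region in regionprops(labels, intensity_image=values):
            if region.area < min_area:
                continue
            r, c = region.centroid
            spots.append((float(r), float(c), int(region.area), float(region.intensity_max), polarity))
    return spots


def detect_events(
    rs: RatioStack, threshold: float, params: EventDetectionParams | None = None
) -> list[DetectedEvent]:
    """Detect events in a ratio stack.

    Per ratio frame, connected components of supra-threshold pixels with
    area >= ``min_spot_area_px`` become candidate spots; candidates of the
    same polarity within ``merge_radius_px`` in ratio frames at most
    ``merge_frames`` apart are merged into one event (earliest frame and
    centroid kept, peak ratio maximized). Events are returned sorted by
    frame, then row, then col.
    """
    params = params or EventDetectionParams()
    if not threshold > 1:
        raise ValueError("threshold must be > 1 for a ratio image")
    # merged[i] = [frame, row, col, area, peak, polarity, last_frame]
    merged: list[list] = []
    for i in range(rs.n_ratio_frames):
        for r, c, area, peak, pol in _frame_spots(
            rs.ratios[i], threshold, params.min_spot_area_px, params.two_sided
        ):
            absorbed = False
            for ev in merged:
                if (
                    ev[5] == pol
                    and i - ev[6] <= params.merge_frames
                    and i > ev[6]
                    and math.hypot(r - ev[1], c - ev[2]) <= params.merge_radius_px
                ):
                    ev[4] = max(ev[4], peak)
                    ev[6] = i
                    absorbed = True
                    break
            if not absorbed:
                merged.append([i, r, c, area, peak, pol, i])
    events = [
        DetectedEvent(frame=f, row=r, col=c, area_px=a, peak_ratio=p, polarity=pol)
        for f, r, c, a, p, pol, _ in merged
    ]
    events.sort(key=lambda e: (e.frame, e.row, e.col))
    return events


def temporal_max_projection(
    rs: RatioStack,
    display_lo: float = 1.3,
    display_hi: float = 3.0,
    png_path=None,
) -> np.ndarray:
    """Per-pixel maximum of the ratio stack over time.

    Returns the raw projection; if ``png_path`` is given, also writes a
    rendering clipped to [display_lo, display_hi] with the perceptual
    ``inferno`` colormap (an approximation of the classic "FIRE" lookup
    table).
    """
    proj = rs.ratios.max(axis=0)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        scaled = np.clip((proj - display_lo) / (display_hi - display_lo), 0.0, 1.0)
        plt.imsave(png_path, scaled, cmap="inferno", vmin=0.0, vmax=1.0)
    return proj


def events_per_filament(
    events: Sequence[DetectedEvent],
    tracks: Sequence[Track],
    max_disp_um: float,
    pixel_size_um: float,
) -> tuple[list[DetectedEvent], float, int]:
    """Assign events to tracks and compute the movie-level event frequency.

    Each event (between source frames i and i+1) is assigned to the track
    whose centroid at frame i or i+1 is nearest, provided that distance is
    within ``max_disp_um``; others stay unassigned. Returns the events with
    ``track_id`` filled in, the frequency (assigned events / n_tracks; 0
    when there are no events), and the unassigned count.
    """
    positions: dict[int, dict[int, tuple[float, float]]] = {
        t.track_id: {p.frame: (p.row, p.col) for p in t.points} for t in tracks
    }
    limit_px = max_disp_um / pixel_size_um
    out: list[DetectedEvent] = []
    assigned = 0
    for ev in events:
        best: tuple[float, int] | None = None
        for tid, frames in positions.items():
            for f in (ev.frame, ev.frame + 1):
                if f in frames:
                    pr, pc = frames[f]
                    d = math.hypot(ev.row - pr, ev.col - pc)
                    if d <= limit_px and (best is None or d < best[0]):
                        best = (d, tid)
        if best is not None:
            assigned += 1
            out.append(
                DetectedEvent(
                    frame=ev.frame, row=ev.row, col=ev.col, area_px=ev.area_px,
                    peak_ratio=ev.peak_ratio, polarity=ev.polarity, kind=ev.kind,
                    track_id=best[1],
                )
            )
        else:
            out.append(ev)
    frequency = assigned / len(tracks) if tracks else float("nan")
    return out, frequency, len(events) - assigned
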