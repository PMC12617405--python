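"""Per-frame filament segmentation and background statistics.

Filaments are separated from background by deterministic thresholding of a
lightly smoothed frame — Otsu's method by default, or a fixed number of
robust background SDs above the robust background level. Background mean
and SD (the inputs to the event-detection threshold) are pooled over the
background pixels of every frame of a movie, giving one pair per movie.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import skeletonize

if TYPE_CHECKING:  # pragma: no cover
    from .io import MovieStack

__all__ = [
    "SegmentationParams",
    "LabeledFrame",
    "FilamentMeasure",
    "DegenerateSegmentationError",
    "segment_frame",
    "measure_filaments",
    "background_stats",
]

#: MAD -> SD conversion for a normal distribution.
_MAD_TO_SD = 1.4826


class DegenerateSegmentationError(RuntimeError):
    """Segmentation left no background pixels to estimate statistics from."""


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs for per-frame filament/background separation.

    blur_sigma_px
        Gaussian pre-smoothing width in pixels (0 disables smoothing).
    threshold_method
        ``"otsu"`` (default) or ``"k_sigma"`` — a threshold k_sigma robust
        background SDs above the robust background level (median + MAD).
    k_sigma
        Multiplier for the ``k_sigma`` method.
    min_area_px
        Smallest connected component kept as a filament.
    """

    blur_sigma_px: float = 1.0
    threshold_method: str = "otsu"
    k_sigma: float = 5.0
    min_area_px: int = 6

    def __post_init__(self) -> None:
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not self.k_sigma > 0:
            raise ValueError("k_sigma must be > 0")
        if self.threshold_method not in ("otsu", "k_sigma"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


@dataclass(frozen=True)
class LabeledFrame:
    """One segmented frame: label image plus that frame's background stats.

    Labels are consecutive positive integers (0 = background); background
    statistics are computed only over label-0 pixels.
    """

    labels: np.ndarray
    background_mean: float
    background_sd: float

    @property
    def n_filaments(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class FilamentMeasure:
    """Geometry of one labeled filament in one frame.

    ``length_um`` is the geodesic path length of the morphological skeleton
    of the filament mask (orthogonal steps count 1 px, diagonal steps √2),
    times the pixel size. The centroid is the unweighted mask centroid in
    (row, col) pixels.
    """

    frame: int
    filament_label: int
    centroid_row: float
    centroid_col: float
    area_px: int
    length_um: float


def _robust_background(frame: np.ndarray) -> tuple[float, float]:
    """Median / scaled-MAD estimate of background level and noise.

    Insensitive to filament pixels as long as they are a minority of the
    frame, which holds at the filament densities of gliding assays.
    """
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, _MAD_TO_SD * mad


def segment_frame(frame: np.ndarray, params: SegmentationParams) -> LabeledFrame:
    """Segment one frame into labeled filaments and background.

    The smoothed frame is thresholded, connected components smaller than
    ``min_area_px`` are dropped, and surviving components are relabeled
    1..K. A constant frame yields zero filaments with SD 0. For the Otsu
    method the threshold is floored at median + 3·robust SD so that
    filament-free noise frames do not produce spurious objects.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")

    if frame.max() == frame.min():
        return LabeledFrame(
            labels=np.zeros(frame.shape, dtype=np.int32),
            background_mean=float(frame.flat[0]),
            background_sd=0.0,
        )

    smoothed = (
        gaussian(frame, sigma=params.blur_sigma_px, preserve_range=True)
        if params.blur_sigma_px > 0
        else frame
    )
    bg_level, bg_noise = _robust_background(smoothed)
    if params.threshold_method == "otsu":
        thr = max(threshold_otsu(smoothed), bg_level + 3.0 * bg_noise)
    else:
        thr = bg_level + params.k_sigma * bg_noise

    mask = smoothed > thr
    labels, n = _cc_label(mask, connectivity=2, return_num=True)
    if n:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas >= params.min_area_px) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
        labels = relabel[labels]

    bg_pixels = frame[labels == 0]
    if bg_pixels.size == 0:
        raise DegenerateSegmentationError("segmentation left no background pixels")
    return LabeledFrame(
        labels=labels.astype(np.int32),
        background_mean=float(bg_pixels.mean()),
        background_sd=float(bg_pixels.std()),
    )


def _skeleton_length_px(mask: np.ndarray) -> float:
    """Geodesic length of the skeleton of a binary mask, in pixels.

    Sums inter-pixel steps along the skeleton: 1 per orthogonal neighbor
    pair, √2 per diagonal pair (diagonal pairs already bridged by an
    orthogonal path are not double-counted by skeletonize's thin output).
    """
    skel = skeletonize(mask)
    if skel.sum() <= 1:
        return 0.0
    s = skel.astype(np.int8)
    n_orth = int(np.sum(s[:, :-1] & s[:, 1:]) + np.sum(s[:-1, :] & s[1:, :]))
    n_diag = int(np.sum(s[:-1, :-1] & s[1:, 1:]) + np.sum(s[:-1, 1:] & s[1:, :-1]))
    return n_orth + np.sqrt(2.0) * n_diag


def measure_filaments(
    lf: LabeledFrame, pixel_size_um: float, frame: int = 0
) -> list[FilamentMeasure]:
    """Measure centroid, area and skeleton length of every label."""
    out: list[FilamentMeasure] = []
    for lab in range(1, lf.n_filaments + 1):
        mask = lf.labels == lab
        rows, cols = np.nonzero(mask)
        out.append(
            FilamentMeasure(
                frame=frame,
                filament_label=lab,
                centroid_row=float(rows.mean()),
                centroid_col=float(cols.mean()),
                area_px=int(mask.sum()),
                length_um=_skeleton_length_px(mask) * pixel_size_um,
            )
        )
    return out


def background_stats(stack: "MovieStack", params: SegmentationParams) -> tuple[float, float]:
    """Movie-level background mean and SD.

    Each frame is segmented independently; the statistics are pooled over
    the background pixels of all frames, producing a single (mean, SD) pair
    per movie — the quantities the event-detection threshold consumes.
    """
    n = 0
    s = 0.0
    ss = 0.0
    for t in range(stack.n_frames):
        frame = np.asarray(stack.frames[t], dtype=float)
        lf = segment_frame(frame, params)
        bg = frame[lf.labels == 0]
        n += bg.size
        s += float(bg.sum())
        ss += float(np.square(bg).sum())
    if n == 0:
        raise DegenerateSegmentationError("no background pixels in any frame")
    mean = s / n
    var = max(ss / n - mean * mean, 0.0)
    return mean, float(np.sqrt(var))
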