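"""Reading and writing the formats the pipeline touches.

Movies are multi-page grayscale TIFF stacks; all tabular output is CSV with
a header row. Physical calibration (pixel size, frame interval) is always
supplied by the caller rather than parsed from TIFF tags, because tag
dialects across acquisition software are unreliable. Image coordinates are
0-based (row, col); frame indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "FormatError",
    "read_movie",
    "write_movie",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Input file exists but is not an acceptable grayscale time-lapse."""


@dataclass(frozen=True)
class MovieStack:
    """A calibrated time-lapse intensity stack.

    Parameters
    ----------
    frames
        Array of shape (T, H, W) with finite, nonnegative intensities in
        arbitrary camera units. Any integer or float grayscale dtype is
        accepted.
    pixel_size_um
        Lateral calibration, micrometres per pixel (> 0).
    frame_interval_s
        Time between consecutive frames, seconds (> 0).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise FormatError(
                f"expected a T x H x W grayscale stack, got shape {frames.shape}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError("movie intensities must be finite")
        if frames.size and frames.min() < 0:
            raise ValueError("movie intensities must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        """Elapsed time from first to last frame."""
        return (self.n_frames - 1) * self.frame_interval_s

    def with_frames(self, frames: np.ndarray) -> "MovieStack":
        """Same calibration, new pixel data."""
        return MovieStack(frames, self.pixel_size_um, self.frame_interval_s)


def read_movie(path: str | Path, pixel_size_um: float, frame_interval_s: float) -> MovieStack:
    """Read a multi-page grayscale TIFF as a :class:`MovieStack`.

    Calibration always comes from the arguments (they override any file
    metadata). Raises :class:`FormatError` for RGB data or stacks with
    fewer than two pages, since every downstream ratio analysis needs at
    least one frame pair.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"could not read TIFF movie at {path}: {exc}") from exc
    except Exception as exc:  # tifffile raises assorted parse errors
        raise OSError(f"corrupt or unreadable TIFF at {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise FormatError(f"{path}: single-page TIFF; a movie needs >= 2 frames")
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {frames.shape} "
            "(RGB or multichannel data is not supported)"
        )
    if frames.shape[0] < 2:
        raise FormatError(f"{path}: movie has {frames.shape[0]} page(s); >= 2 required")
    return MovieStack(frames, pixel_size_um, frame_interval_s)


def write_movie(stack: MovieStack, path: str | Path) -> Path:
    """Write a movie as an uncompressed multi-page grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    return path


#: float format used for all CSV output: >= 6 significant digits, no
#: spurious trailing zeros.
_CSV_FLOAT_FORMAT = "%.8g"


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> Path:
    """Write flat records as a CSV with a header row.

    An empty record list still produces a header-only file when a DataFrame
    (which carries its columns) is passed; a plain empty list produces an
    empty file with no columns to name.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    try:
        df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
    except OSError as exc:
        raise OSError(f"could not write table to {path}: {exc}") from exc
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table`."""
    return pd.read_csv(path)
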