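"""Ground-truthed synthetic data for every pipeline stage.

Three generators emulate the measurement situations the pipeline is built
for:

* :func:`simulate_gliding_movie` — fluorescent filaments on a myosin lawn:
  smooth random curves gliding along their own contour, with Poisson-timed
  wobble (abrupt lateral jump) and detachment (disappearance) events,
  rendered through a Gaussian PSF over noisy background. Returns the movie
  together with the exact trajectories and event list, the oracle for the
  segmentation, tracking and event-detection stages.
* :func:`simulate_cells` — cohorts of rod-shaped cell dimensions drawn from
  normal length/width distributions, the input to morphometry.
* :func:`simulate_ring_traces` — per-cell cytokinetic-ring state/diameter
  time series with normally distributed phase durations sampled on the
  imaging grid, the input to phase timing.

Defaults for the cell cohorts and ring traces are the published per-strain
statistics of the MEEE (wild-type N terminus) and REE (arginylated) actin
strains; the gliding defaults describe a 1 s / 60 s non-muscle-myosin assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import MovieStack
from .morphometry import CellDims
from .ringtiming import PhaseDurations, RingTrace

__all__ = [
    "ParameterError",
    "GlidingSimConfig",
    "TrueEvent",
    "TrueFilament",
    "GroundTruth",
    "simulate_gliding_movie",
    "simulate_cells",
    "CELL_PRESETS",
    "RingSimConfig",
    "RING_PRESETS",
    "simulate_ring_traces",
]


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


# ---------------------------------------------------------------------------
# gliding-filament movies
# ---------------------------------------------------------------------------

#: contour sampling step, px of arc length
_DS_PX = 0.25
#: SD of the tangent-angle random walk, rad per sqrt(px of arc)
_KAPPA_SD = 0.05
#: frame margin (in PSF sigmas) kept clear when placing filaments
_MARGIN_SIGMAS = 3.0


@dataclass(frozen=True)
class GlidingSimConfig:
    """Parameters of a synthetic gliding-assay movie.

    Geometry is in micrometres, converted internally with
    ``pixel_size_um``. ``motile_fraction`` of the filaments glide along
    their own contour at ``speed_um_per_s``; wobble and detachment events
    occur as Poisson processes with the given per-filament rates while a
    filament is attached. ``filament_amplitude`` is the peak rendered
    intensity above background after PSF convolution; the background is
    ``background_mean`` plus Gaussian noise of SD ``background_sd``.
    """

    n_filaments: int = 10
    length_mean_um: float = 3.0
    length_sd_um: float = 1.0
    speed_um_per_s: float = 0.1
    motile_fraction: float = 0.6
    wobble_rate_per_s: float = 0.02
    detach_rate_per_s: float = 0.01
    wobble_jump_um: float = 1.0
    psf_sigma_px: float = 1.5
    background_mean: float = 100.0
    background_sd: float = 6.0
    filament_amplitude: float = 60.0
    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.108
    frame_interval_s: float = 1.0
    n_frames: int = 60
    min_separation_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filaments < 0:
            raise ParameterError("n_filaments must be >= 0")
        if self.wobble_rate_per_s < 0 or self.detach_rate_per_s < 0:
            raise ParameterError("event rates must be >= 0")
        if not 0 <= self.motile_fraction <= 1:
            raise ParameterError("motile_fraction must be in [0, 1]")
        if not self.psf_sigma_px > 0:
            raise ParameterError("psf_sigma_px must be > 0")
        if not self.background_mean > 0:
            raise ParameterError("background_mean must be > 0")
        if self.background_sd < 0:
            raise ParameterError("background_sd must be >= 0")
        if not self.pixel_size_um > 0 or not self.frame_interval_s > 0:
            raise ParameterError("pixel_size_um and frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.length_sd_um < 0:
            raise ParameterError("length_sd_um must be >= 0")
        fov_um = min(self.image_shape) * self.pixel_size_um
        if self.length_mean_um + 3 * self.length_sd_um > fov_um:
            raise ParameterError(
                f"filaments of length up to {self.length_mean_um + 3 * self.length_sd_um:.2f} "
                f"um do not fit a {fov_um:.2f} um field of view"
            )


@dataclass(frozen=True)
class TrueEvent:
    """One ground-truth wobble or detachment.

    ``(row, col)`` is where the change becomes visible: the post-jump
    filament centroid for a wobble, the vacated centroid for a detachment.
    ``(row_alt, col_alt)`` is the complementary position (pre-jump centroid
    for a wobble; identical to the primary one for a detachment).
    ``frame`` is the first frame showing the new configuration, in
    [1, n_frames - 1].
    """

    filament_id: int
    frame: int
    kind: str  # "wobble" | "detach"
    row: float
    col: float
    row_alt: float
    col_alt: float


@dataclass
class TrueFilament:
    """Exact trajectory of one simulated filament."""

    filament_id: int
    motile: bool
    speed_um_per_s: float
    present: np.ndarray  # (T,) bool
    centroids: np.ndarray  # (T, 2) row/col px, NaN while absent
    _path: np.ndarray  # (N, 2) full glide path, px
    _arc_index: np.ndarray  # (T,) start index into _path
    _offsets: np.ndarray  # (T, 2) accumulated wobble displacement, px
    n_contour: int

    def contour_at(self, t: int) -> np.ndarray | None:
        """Contour points (n, 2) at frame ``t``, or None when absent."""
        if not self.present[t]:
            return None
        i0 = int(self._arc_index[t])
        return self._path[i0 : i0 + self.n_contour] + self._offsets[t]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    filaments: list[TrueFilament]
    events: list[TrueEvent]
    signal: np.ndarray  # (T, H, W) noiseless rendered signal, no background
    config: GlidingSimConfig

    def live_counts(self) -> np.ndarray:
        """Number of attached filaments per frame."""
        T = self.config.n_frames
        counts = np.zeros(T, dtype=int)
        for f in self.filaments:
            counts += f.present
        return counts

    def mask(self, t: int, rel_level: float = 0.5) -> np.ndarray:
        """True filament pixels of frame ``t`` (signal above a fraction of peak)."""
        return self.signal[t] > rel_level * self.config.filament_amplitude


def _random_path(rng: np.random.Generator, n_points: int) -> np.ndarray:
    """Smooth random curve: tangent-angle random walk, unit-speed arc."""
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    dtheta = rng.normal(0.0, _KAPPA_SD * np.sqrt(_DS_PX), size=max(n_points - 1, 1))
    theta = theta0 + np.concatenate(([0.0], np.cumsum(dtheta)))[:n_points]
    steps = _DS_PX * np.column_stack([np.sin(theta), np.cos(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps[:-1], axis=0)])
    return pts


def _place_path(
    rng: np.random.Generator,
    path: np.ndarray,
    shape: tuple[int, int],
    margin: float,
    placed: list[np.ndarray],
    min_sep_px: float | None,
) -> np.ndarray:
    """Translate a path to a random in-bounds position, optionally keeping
    a minimum distance from previously placed paths."""
    lo = path.min(axis=0)
    hi = path.max(axis=0)
    for _ in range(100):
        offs = np.empty(2)
        ok = True
        for ax, dim in enumerate(shape):
            a = margin - lo[ax]
            b = dim - 1 - margin - hi[ax]
            if b < a:  # path sweep larger than field: center it
                offs[ax] = (dim - 1 - (lo[ax] + hi[ax])) / 2.0
            else:
                offs[ax] = rng.uniform(a, b)
        candidate = path + offs
        if min_sep_px is not None:
            sub = candidate[::8]
            for other in placed:
                d2 = np.min(
                    np.sum((sub[:, None, :] - other[None, ::8, :]) ** 2, axis=-1)
                )
                if d2 < min_sep_px**2:
                    ok = False
                    break
        if ok:
            return candidate
    return candidate  # give up on separation after 100 tries


def _stamp(img: np.ndarray, pts: np.ndarray, mass: float) -> None:
    """Bilinear deposition of equal point masses into ``img`` (in place)."""
    h, w = img.shape
    r, c = pts[:, 0], pts[:, 1]
    keep = (r > -1) & (r < h) & (c > -1) & (c < w)
    r, c = r[keep], c[keep]
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr, fc = r - r0, c - c0
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(img, (rr[ok], cc[ok]), mass * wgt[ok])


def simulate_gliding_movie(config: GlidingSimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a gliding-assay movie and return it with its ground truth.

    Deterministic given ``config.seed``. Filament contours are smooth
    random curves; motile filaments advance along their own path at the
    configured speed; wobbles displace the whole filament laterally within
    one frame (the offset persists); detached filaments vanish for all
    later frames.
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_frames
    H, W = config.image_shape
    px = config.pixel_size_um
    dt = config.frame_interval_s
    margin = _MARGIN_SIGMAS * config.psf_sigma_px
    min_sep_px = (
        config.min_separation_um / px if config.min_separation_um is not None else None
    )
    speed_px = config.speed_um_per_s / px * dt  # px per frame
    jump_px = config.wobble_jump_um / px
    fov_um = min(H, W) * px

    filaments: list[TrueFilament] = []
    events: list[TrueEvent] = []
    placed_paths: list[np.ndarray] = []

    for fid in range(config.n_filaments):
        length_um = float(
            np.clip(
                rng.normal(config.length_mean_um, config.length_sd_um),
                0.5,
                fov_um - 1.0,
            )
        )
        n_contour = max(int(round(length_um / px / _DS_PX)), 2)
        motile = bool(rng.random() < config.motile_fraction)

        # detachment: first arrival of a Poisson process; visible events
        # only in [1, T-1]
        detach_frame: int | None = None
        if config.detach_rate_per_s > 0:
            t_detach = rng.exponential(1.0 / config.detach_rate_per_s)
            f = int(t_detach / dt) + 1
            if f <= T - 1:
                detach_frame = f

        # wobbles while attached
        attached_duration = ((detach_frame if detach_frame is not None else T) - 1) * dt
        wobble_frames: list[int] = []
        if config.wobble_rate_per_s > 0 and attached_duration > 0:
            n_wob = rng.poisson(config.wobble_rate_per_s * attached_duration)
            times = np.sort(rng.uniform(0.0, attached_duration, size=n_wob))
            wobble_frames = [min(int(t / dt) + 1, T - 1) for t in times]

        # wobble jump signs drawn up front so the placement margin can
        # absorb the largest cumulative lateral excursion
        wobble_signs = np.where(rng.random(len(wobble_frames)) < 0.5, 1.0, -1.0)
        excursion = (
            jump_px * float(np.max(np.abs(np.cumsum(wobble_signs))))
            if len(wobble_frames)
            else 0.0
        )

        glide_len = speed_px * (T - 1) if motile else 0.0
        n_path = n_contour + int(np.ceil(glide_len / _DS_PX)) + 2
        path = _random_path(rng, n_path)
        path = _place_path(rng, path, (H, W), margin + excursion, placed_paths, min_sep_px)
        placed_paths.append(path)

        present = np.ones(T, dtype=bool)
        if detach_frame is not None:
            present[detach_frame:] = False
        arc_index = (
            np.round(np.arange(T) * speed_px / _DS_PX).astype(int)
            if motile
            else np.zeros(T, dtype=int)
        )
        arc_index = np.minimum(arc_index, len(path) - n_contour)

        # persistent lateral offsets from wobbles
        offsets = np.zeros((T, 2))
        direction = path[-1] - path[0]
        nrm = np.linalg.norm(direction)
        perp = (
            np.array([-direction[1], direction[0]]) / nrm
            if nrm > 0
            else np.array([1.0, 0.0])
        )
        for wf, sign in zip(wobble_frames, wobble_signs):
            offsets[wf:] += sign * jump_px * perp

        centroids = np.full((T, 2), np.nan)
        fil = TrueFilament(
            filament_id=fid,
            motile=motile,
            speed_um_per_s=config.speed_um_per_s if motile else 0.0,
            present=present,
            centroids=centroids,
            _path=path,
            _arc_index=arc_index,
            _offsets=offsets,
            n_contour=n_contour,
        )
        for t in range(T):
            pts = fil.contour_at(t)
            if pts is not None:
                centroids[t] = pts.mean(axis=0)

        for wf in wobble_frames:
            if present[wf]:
                events.append(
                    TrueEvent(
                        filament_id=fid,
                        frame=wf,
                        kind="wobble",
                        row=centroids[wf, 0],
                        col=centroids[wf, 1],
                        row_alt=centroids[wf - 1, 0],
                        col_alt=centroids[wf - 1, 1],
                    )
                )
        if detach_frame is not None:
            events.append(
                TrueEvent(
                    filament_id=fid,
                    frame=detach_frame,
                    kind="detach",
                    row=centroids[detach_frame - 1, 0],
                    col=centroids[detach_frame - 1, 1],
                    row_alt=centroids[detach_frame - 1, 0],
                    col_alt=centroids[detach_frame - 1, 1],
                )
            )
        filaments.append(fil)

    # render: unit-length line mass chosen so the PSF-convolved ridge peak
    # equals filament_amplitude
    mass = config.filament_amplitude * config.psf_sigma_px * np.sqrt(2.0 * np.pi) * _DS_PX
    signal = np.zeros((T, H, W), dtype=np.float32)
    for t in range(T):
        img = np.zeros((H, W))
        for fil in filaments:
            pts = fil.contour_at(t)
            if pts is not None:
                _stamp(img, pts, mass)
        signal[t] = gaussian_filter(img, config.psf_sigma_px, mode="constant")

    noise = rng.normal(0.0, config.background_sd, size=(T, H, W))
    frames = np.maximum(signal + config.background_mean + noise, 0.0)
    movie = MovieStack(frames, pixel_size_um=px, frame_interval_s=dt)
    events.sort(key=lambda e: (e.frame, e.filament_id))
    return movie, GroundTruth(filaments=filaments, events=events, signal=signal, config=config)


# ---------------------------------------------------------------------------
# cell-dimension cohorts
# ---------------------------------------------------------------------------

#: published per-strain dimension statistics (mean, SD in um) of septated
#: cells: MEEE = wild-type N terminus, REE = arginylated actin.
CELL_PRESETS: dict[str, dict[str, float]] = {
    "MEEE": dict(length_mean_um=13.54, length_sd_um=0.98, width_mean_um=4.10, width_sd_um=0.27),
    "REE": dict(length_mean_um=11.76, length_sd_um=0.90, width_mean_um=4.24, width_sd_um=0.31),
}


def simulate_cells(
    n: int,
    length_mean_um: float,
    length_sd_um: float,
    width_mean_um: float,
    width_sd_um: float,
    seed: int = 0,
    strain: str = "cohort",
) -> list[CellDims]:
    """Draw a cohort of cell dimensions.

    Lengths and widths are independent normals, resampled until
    length > width > 0. SD = 0 gives a degenerate (identical) cohort.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if length_mean_um <= 0 or width_mean_um <= 0:
        raise ParameterError("means must be > 0")
    if length_sd_um < 0 or width_sd_um < 0:
        raise ParameterError("SDs must be >= 0 (0 allowed: degenerate cohort)")
    if length_sd_um == 0 and width_sd_um == 0 and not (length_mean_um > width_mean_um > 0):
        raise ParameterError("degenerate cohort requires length_mean > width_mean > 0")
    rng = np.random.default_rng(seed)
    cells: list[CellDims] = []
    for i in range(n):
        while True:
            L = rng.normal(length_mean_um, length_sd_um)
            w = rng.normal(width_mean_um, width_sd_um)
            if L > w > 0:
                break
        cells.append(CellDims(cell_id=f"{strain}_{i:04d}", strain=strain, length_um=L, width_um=w))
    return cells


# ---------------------------------------------------------------------------
# cytokinetic-ring traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSimConfig:
    """Per-strain generative model for ring traces.

    Phase durations are normal draws rounded to the nearest positive
    multiple of ``frame_interval_min`` — ring-state transitions are only
    observable on the imaging grid, and published per-cell timings are
    multiples of the 3-min sampling. The initial ring diameter (roughly the
    cell width at division) defaults to 3.7 ± 0.2 μm.
    """

    strain: str = "REE"
    coalescence_mean_min: float = 20.52
    coalescence_sd_min: float = 2.69
    dwell_mean_min: float = 5.64
    dwell_sd_min: float = 2.64
    constriction_mean_min: float = 45.48
    constriction_sd_min: float = 12.27
    diameter_mean_um: float = 3.7
    diameter_sd_um: float = 0.2
    frame_interval_min: float = 3.0
    n_cells: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coalescence_mean_min", "dwell_mean_min", "constriction_mean_min",
                     "diameter_mean_um", "frame_interval_min"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("coalescence_sd_min", "dwell_sd_min", "constriction_sd_min",
                     "diameter_sd_um"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")


#: published per-strain phase statistics (minutes; constriction rate in
#: um/min follows from diameter/constriction). 25 cells each at 3-min
#: sampling in the source data.
RING_PRESETS: dict[str, RingSimConfig] = {
    "REE": RingSimConfig(
        strain="REE",
        coalescence_mean_min=20.52, coalescence_sd_min=2.69,
        dwell_mean_min=5.64, dwell_sd_min=2.64,
        constriction_mean_min=45.48, constriction_sd_min=12.27,
    ),
    "MEEE": RingSimConfig(
        strain="MEEE",
        coalescence_mean_min=16.20, coalescence_sd_min=2.12,
        dwell_mean_min=8.88, dwell_sd_min=2.52,
        constriction_mean_min=34.32, constriction_sd_min=6.66,
    ),
}


def _draw_grid_duration(rng: np.random.Generator, mean: float, sd: float, dt: float) -> float:
    """Normal draw snapped to the nearest positive multiple of the frame interval."""
    x = rng.normal(mean, sd)
    return max(round(x / dt), 1) * dt


def simulate_ring_traces(config: RingSimConfig) -> list[tuple[RingTrace, PhaseDurations]]:
    """Generate per-cell ring traces paired with their exact generating durations.

    Each trace runs from node appearance (t = 0) to ring closure: state
    ``nodes`` during coalescence, ``ring`` at the constant initial diameter
    during dwell, linearly decreasing diameter during constriction, and a
    final ``done`` sample at closure.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_min
    out: list[tuple[RingTrace, PhaseDurations]] = []
    for i in range(config.n_cells):
        coal = _draw_grid_duration(rng, config.coalescence_mean_min, config.coalescence_sd_min, dt)
        dwell = _draw_grid_duration(rng, config.dwell_mean_min, config.dwell_sd_min, dt)
        con = _draw_grid_duration(rng, config.constriction_mean_min, config.constriction_sd_min, dt)
        diameter = max(rng.normal(config.diameter_mean_um, config.diameter_sd_um), 1.0)
        total = coal + dwell + con
        times = np.arange(0.0, total + dt / 2, dt)
        states: list[str] = []
        diams = np.full(times.size, np.nan)
        for j, t in enumerate(times):
            if t < coal:
                states.append("nodes")
            elif t < coal + dwell:
                states.append("ring")
                diams[j] = diameter
            elif t < total:
                states.append("ring")
                diams[j] = diameter * (1.0 - (t - coal - dwell) / con)
            else:
                states.append("done")
        cell_id = f"{config.strain}_{i:03d}"
        trace = RingTrace(
            cell_id=cell_id,
            strain=config.strain,
            times_min=times,
            states=tuple(states),
            diameters_um=diams,
            frame_interval_min=dt,
        )
        truth = PhaseDurations.from_phases(
            coalescence_min=coal,
            dwell_min=dwell,
            constriction_min=con,
            initial_diameter_um=diameter,
            cell_id=cell_id,
            strain=config.strain,
        )
        out.append((trace, truth))
    return out
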