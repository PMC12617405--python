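"""Cytokinetic-ring phase timing for fission yeast.

The cytokinetic actomyosin ring (CAR) passes through three sequential
phases: precursor nodes appear and coalesce into a ring (node coalescence),
the assembled ring pauses at constant diameter (dwell), then constricts to
closure (constriction). Given a per-cell time series of ring state and
diameter sampled on a regular imaging grid, this module segments the trace
into the three phases with reproducible changepoint rules, computes the
total cytokinesis time and the average constriction rate (initial ring
diameter divided by constriction time), and summarizes cohorts per strain.

All durations are reported as multiples of the sampling interval: the data
are typically 3-min time lapses and sub-frame timing is not resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RingTrace",
    "PhaseTimingParams",
    "PhaseDurations",
    "MalformedTraceError",
    "CensoredTraceError",
    "segment_phases",
    "analyze_traces",
    "summarize_phases",
]

#: allowed ring states, in temporal order
STATES = ("nodes", "ring", "done")


class MalformedTraceError(ValueError):
    """Trace violates the nodes -> ring -> done state grammar."""


class CensoredTraceError(RuntimeError):
    """Constriction did not complete within the trace."""


@dataclass(frozen=True)
class RingTrace:
    """One cell's ring state / diameter time series.

    ``times_min`` must be a strictly increasing regular grid with spacing
    ``frame_interval_min``. ``states`` hold ``nodes``/``ring``/``done`` in
    that order of first appearance; ``diameters_um`` holds the ring
    diameter where the state is ``ring`` and NaN elsewhere.
    """

    cell_id: str
    strain: str
    times_min: np.ndarray
    states: tuple[str, ...]
    diameters_um: np.ndarray
    frame_interval_min: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        d = np.asarray(self.diameters_um, dtype=float)
        if t.ndim != 1 or len(self.states) != t.size or d.size != t.size:
            raise MalformedTraceError("times, states and diameters must align")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, self.frame_interval_min):
                raise MalformedTraceError("times must increase on a regular grid")
        for s in self.states:
            if s not in STATES:
                raise MalformedTraceError(f"unknown state {s!r}")
        order = [STATES.index(s) for s in self.states]
        if np.any(np.diff(order) < 0):
            raise MalformedTraceError("states must appear in order nodes -> ring -> done")
        ring = np.array([s == "ring" for s in self.states])
        if np.any(ring & ~(d > 0)):
            raise MalformedTraceError("diameter must be > 0 wherever state is 'ring'")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "diameters_um", d)
        object.__setattr__(self, "states", tuple(self.states))


@dataclass(frozen=True)
class PhaseTimingParams:
    """Changepoint rules for phase segmentation.

    dwell_tolerance_frac
        Fractional diameter drop (relative to the initial ring diameter)
        that marks the onset of constriction; diameters within this
        fraction of the initial value still count as dwell.
    smoothing_window
        Odd window (frames) for median smoothing of the diameter series and
        for the initial-diameter estimate.
    end_diameter_um
        Constriction is considered complete once the diameter falls below
        this, for traces that lack an explicit ``done`` state.
    """

    dwell_tolerance_frac: float = 0.05
    smoothing_window: int = 3
    end_diameter_um: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.dwell_tolerance_frac < 1:
            raise ValueError("dwell_tolerance_frac must be in (0, 1)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if not self.end_diameter_um > 0:
            raise ValueError("end_diameter_um must be > 0")


@dataclass(frozen=True)
class PhaseDurations:
    """Per-cell phase durations (minutes) and derived constriction rate.

    Invariants enforced: ``total_min`` equals the exact sum of the three
    phases, and ``rate_um_per_min`` times ``constriction_min`` equals the
    initial diameter.
    """

    cell_id: str
    strain: str
    coalescence_min: float
    dwell_min: float
    constriction_min: float
    total_min: float
    initial_diameter_um: float
    rate_um_per_min: float

    def __post_init__(self) -> None:
        if self.coalescence_min <= 0 or self.constriction_min <= 0:
            raise ValueError("coalescence and constriction durations must be > 0")
        if self.dwell_min < 0:
            raise ValueError("dwell duration must be >= 0")
        s = self.coalescence_min + self.dwell_min + self.constriction_min
        if self.total_min != s:
            raise ValueError("total_min must equal the exact sum of the phases")
        if self.initial_diameter_um <= 0:
            raise ValueError("initial diameter must be > 0")
        expected_rate = self.initial_diameter_um / self.constriction_min
        if abs(self.rate_um_per_min - expected_rate) > 1e-9 * max(expected_rate, 1.0):
            raise ValueError("rate must equal initial diameter / constriction time")

    @classmethod
    def from_phases(
        cls,
        coalescence_min: float,
        dwell_min: float,
        constriction_min: float,
        initial_diameter_um: float,
        cell_id: str = "",
        strain: str = "",
    ) -> "PhaseDurations":
        return cls(
            cell_id=cell_id,
            strain=strain,
            coalescence_min=coalescence_min,
            dwell_min=dwell_min,
            constriction_min=constriction_min,
            total_min=coalescence_min + dwell_min + constriction_min,
            initial_diameter_um=initial_diameter_um,
            rate_um_per_min=initial_diameter_um / constriction_min,
        )


def _median_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; the window shrinks at the edges."""
    if window <= 1 or values.size <= 2:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def segment_phases(trace: RingTrace, params: PhaseTimingParams | None = None) -> PhaseDurations:
    """Segment one trace into coalescence / dwell / constriction.

    Rules (all on the sampling grid):

    * coalescence — from the first ``nodes`` sample to the first ``ring``
      sample;
    * initial diameter — median of the first ``smoothing_window`` ring
      diameters;
    * constriction onset — the ring sample preceding the first sample whose
      median-smoothed diameter has dropped more than ``dwell_tolerance_frac``
      below the initial diameter (the diameter at the onset frame itself is
      still the initial one; the drop becomes visible one frame later);
    * end of constriction — the first ``done`` sample, or, for traces
      without one, the first ring sample with diameter below
      ``end_diameter_um``.

    Raises :class:`MalformedTraceError` if a required state is missing and
    :class:`CensoredTraceError` if constriction never completes.
    """
    params = params or PhaseTimingParams()
    states = np.asarray(trace.states)
    t = trace.times_min

    nodes_idx = np.flatnonzero(states == "nodes")
    ring_idx = np.flatnonzero(states == "ring")
    done_idx = np.flatnonzero(states == "done")
    if nodes_idx.size == 0 or ring_idx.size == 0:
        raise MalformedTraceError(
            f"trace {trace.cell_id!r} lacks a 'nodes' or 'ring' phase"
        )
    if ring_idx.size < 2:
        raise MalformedTraceError(f"trace {trace.cell_id!r} has < 2 ring samples")

    coalescence = t[ring_idx[0]] - t[nodes_idx[0]]

    diam = trace.diameters_um[ring_idx]
    smoothed = _median_smooth(diam, params.smoothing_window)
    initial = float(np.median(diam[: params.smoothing_window]))

    below = np.flatnonzero(smoothed < (1.0 - params.dwell_tolerance_frac) * initial)
    if below.size == 0 and done_idx.size == 0:
        raise CensoredTraceError(f"trace {trace.cell_id!r}: no constriction observed")
    # onset = sample before the first supra-tolerance drop, clamped to ring start
    onset_ring_pos = max(int(below[0]) - 1, 0) if below.size else len(diam) - 1
    onset_time = t[ring_idx[onset_ring_pos]]
    dwell = onset_time - t[ring_idx[0]]

    if done_idx.size:
        end_time = t[done_idx[0]]
    else:
        finished = np.flatnonzero(diam < params.end_diameter_um)
        if finished.size == 0:
            raise CensoredTraceError(
                f"trace {trace.cell_id!r}: diameter never fell below "
                f"{params.end_diameter_um} um and no 'done' state present"
            )
        end_time = t[ring_idx[finished[0]]]
    constriction = end_time - onset_time
    if constriction <= 0:
        raise CensoredTraceError(
            f"trace {trace.cell_id!r}: constriction window is empty"
        )

    return PhaseDurations.from_phases(
        coalescence_min=float(coalescence),
        dwell_min=float(dwell),
        constriction_min=float(constriction),
        initial_diameter_um=initial,
        cell_id=trace.cell_id,
        strain=trace.strain,
    )


def analyze_traces(
    traces: Sequence[RingTrace], params: PhaseTimingParams | None = None
) -> tuple[list[PhaseDurations], int]:
    """Segment many traces, skipping censored ones.

    Returns the uncensored per-cell durations and the number of censored
    traces excluded.
    """
    out: list[PhaseDurations] = []
    censored = 0
    for trace in traces:
        try:
            out.append(segment_phases(trace, params))
        except CensoredTraceError:
            censored += 1
    return out, censored


_QUANTITIES = {
    "coalescence_min": "coalescence_min",
    "dwell_min": "dwell_min",
    "constriction_min": "constriction_min",
    "total_min": "total_min",
    "rate_um_per_min": "rate_um_per_min",
}


def summarize_phases(
    durations: Sequence[PhaseDurations], min_cells: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-strain mean ± SD of each phase quantity, plus two-sample tests.

    Returns ``(summary, tests)``. ``tests`` holds rank-sum (Mann-Whitney,
    normal approximation with tie correction) and Welch t statistics for
    every strain pair and quantity; it is ``None`` when only one strain is
    present.
    """
    if not durations:
        raise ValueError("no uncensored cells to summarize")
    df = pd.DataFrame(
        {
            "cell_id": [d.cell_id for d in durations],
            "strain": [d.strain for d in durations],
            **{col: [getattr(d, col) for d in durations] for col in _QUANTITIES},
        }
    )
    counts = df.groupby("strain").size()
    lacking = counts[counts < min_cells]
    if not lacking.empty:
        raise ValueError(
            f"strains with < {min_cells} uncensored cells: {list(lacking.index)}"
        )
    summary = df.groupby("strain")[list(_QUANTITIES)].agg(["count", "mean", "std"])

    strains = sorted(df["strain"].unique())
    if len(strains) < 2:
        return summary, None
    rows = []
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            for col in _QUANTITIES:
                xa = df.loc[df["strain"] == a, col].to_numpy()
                xb = df.loc[df["strain"] == b, col].to_numpy()
                u = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
                tt = stats.ttest_ind(xa, xb, equal_var=False)
                rows.append(
                    {
                        "strain_a": a,
                        "strain_b": b,
                        "quantity": col,
                        "ranksum_p": float(u.pvalue),
                        "t_stat": float(tt.statistic),
                        "t_p": float(tt.pvalue),
                    }
                )
    return summary, pd.DataFrame(rows)
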