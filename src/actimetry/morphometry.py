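"""Spherocylinder morphometry of rod-shaped (fission-yeast) cells.

A septated *S. pombe* cell is modeled as a spherocylinder: a cylinder of
diameter w capped by two hemispheres, with the total cell length L
including the caps. Volume and surface area follow in closed form:

    V  = pi (w/2)^2 (L - w) + 4/3 pi (w/2)^3
    SA = 2 pi (w/2) (L - w) + 4 pi (w/2)^2

At L = w both reduce to the sphere formulas. Cohort summaries average the
per-cell values (the formulas are nonlinear, so this differs slightly from
evaluating at the cohort mean dimensions) and compare strains with the
rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellDims",
    "MorphometryRecord",
    "cell_volume",
    "cell_surface_area",
    "summarize_morphometry",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellDims:
    """One septated cell's length and width, micrometres.

    A spherocylinder's length includes its hemispherical caps, so
    ``length_um >= width_um > 0`` is required.
    """

    cell_id: str
    strain: str
    length_um: float
    width_um: float

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise ValueError(f"cell {self.cell_id!r}: width must be > 0")
        if self.length_um < self.width_um:
            raise ValueError(
                f"cell {self.cell_id!r}: length ({self.length_um}) must be >= "
                f"width ({self.width_um})"
            )


@dataclass(frozen=True)
class MorphometryRecord:
    cell_id: str
    strain: str
    length_um: float
    width_um: float
    volume_um3: float
    surface_area_um2: float


def cell_volume(length_um: float, width_um: float) -> float:
    """Spherocylinder volume, cubic micrometres."""
    _check_dims(length_um, width_um)
    r = width_um / 2.0
    return np.pi * r * r * (length_um - width_um) + (4.0 / 3.0) * np.pi * r**3


def cell_surface_area(length_um: float, width_um: float) -> float:
    """Spherocylinder surface area, square micrometres."""
    _check_dims(length_um, width_um)
    r = width_um / 2.0
    return 2.0 * np.pi * r * (length_um - width_um) + 4.0 * np.pi * r * r


def _check_dims(length_um: float, width_um: float) -> None:
    if not width_um > 0:
        raise ValueError("width must be > 0")
    if length_um < width_um:
        raise ValueError("length must be >= width for a spherocylinder")


def compute_morphometry(cells: Iterable[CellDims]) -> list[MorphometryRecord]:
    """Per-cell volume and surface area for a cohort."""
    return [
        MorphometryRecord(
            cell_id=c.cell_id,
            strain=c.strain,
            length_um=c.length_um,
            width_um=c.width_um,
            volume_um3=cell_volume(c.length_um, c.width_um),
            surface_area_um2=cell_surface_area(c.length_um, c.width_um),
        )
        for c in cells
    ]


_PARAMS = ("length_um", "width_um", "volume_um3", "surface_area_um2")


def summarize_morphometry(
    cells: Sequence[CellDims], min_cells: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain mean ± SD and pairwise rank-sum tests.

    Per-cell volume and surface area are computed first, then averaged per
    strain. Cells violating length >= width are dropped with a warning
    rather than failing the cohort. Requires >= 2 strains with >=
    ``min_cells`` cells each. Rank-sum p-values use the normal
    approximation with tie correction.
    """
    valid: list[CellDims] = []
    for c in cells:
        try:
            _check_dims(c.length_um, c.width_um)
        except ValueError as exc:
            logger.warning("dropping cell %r: %s", c.cell_id, exc)
            continue
        valid.append(c)
    records = compute_morphometry(valid)
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty or df["strain"].nunique() < 2:
        raise ValueError("need >= 2 strains with valid cells")
    counts = df.groupby("strain").size()
    lacking = counts[counts < min_cells]
    if not lacking.empty:
        raise ValueError(f"strains with < {min_cells} cells: {list(lacking.index)}")

    summary = df.groupby("strain")[list(_PARAMS)].agg(["count", "mean", "std"])

    strains = sorted(df["strain"].unique())
    rows = []
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            for col in _PARAMS:
                xa = df.loc[df["strain"] == a, col].to_numpy()
                xb = df.loc[df["strain"] == b, col].to_numpy()
                u = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
                rows.append(
                    {
                        "strain_a": a,
                        "strain_b": b,
                        "parameter": col,
                        "ranksum_p": float(u.pvalue),
                    }
                )
    return summary, pd.DataFrame(rows)
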