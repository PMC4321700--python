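"""Fractal-style coarse-graining of trajectories: L_delta and L_delta/L_0.

A coarse-grained trajectory is the polyline through dividing points placed
every ``delta`` of arc length along the original track (positions linearly
interpolated on the polyline, never snapped to samples); its length is
L_delta. The ratio L_delta/L_0, with L_0 the analyzed track length (here
the first 30 mm of each track), quantifies how directional the movement
is: straight tracks keep the ratio at 1 at every delta, while animals
circling in narrow areas lose length rapidly as delta grows.

Cohorts are summarized by the per-delta median of log10(L_delta/L_0) with
first/third quartiles, suitable for log-log plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .trajectory_core import Trajectory, truncate_by_path_length
from ._geometry import cumulative_arclength


@dataclass
class CoarseGrainResult:
    """Coarse-grained length curve of one animal over a delta grid."""

    animal_id: str
    delta_mm: np.ndarray
    L_delta_mm: np.ndarray
    ratio: np.ndarray  # L_delta / L0, dimensionless (A.U.)
    L0_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "delta_mm": self.delta_mm,
                "L_delta_mm": self.L_delta_mm,
                "ratio": self.ratio,
            }
        )


@dataclass
class CohortLogSummary:
    """Per-delta median and quartiles of log10(L_delta/L_0) across animals.

    Quartiles use linear interpolation (the common "type 7" definition);
    an n=1 cohort reports q1 = q3 = median.
    """

    delta_mm: np.ndarray
    median_log10_ratio: np.ndarray
    q1_log10_ratio: np.ndarray
    q3_log10_ratio: np.ndarray
    n_animals: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_mm": self.delta_mm,
                "median_log10": self.median_log10_ratio,
                "q1_log10": self.q1_log10_ratio,
                "q3_log10": self.q3_log10_ratio,
                "n": self.n_animals,
            }
        )


def default_delta_grid(L0: float = 30.0, n: int = 10, smallest: float = 0.5) -> np.ndarray:
    """Logarithmically spaced delta grid from ``smallest`` to ``L0``."""
    return np.geomspace(smallest, L0, n)


def coarse_grain(
    traj: Trajectory, delta_mm: float, L0: float = 30.0
) -> tuple[np.ndarray, float]:
    """Dividing points and coarse-grained length L_delta for one delta.

    The analysis is restricted to the first ``L0`` of path. Dividing points
    sit at arc lengths 0, delta, 2*delta, ...; the point at arc length L0
    is always appended so the chord chain spans the full analyzed length
    (the final partial sub-trajectory contributes one chord; dropping it
    would make L_delta discontinuous in delta).

    Returns
    -------
    points : ndarray of shape (k, 2)
    L_delta : float
    """
    if delta_mm <= 0 or delta_mm > L0:
        raise ParameterError(f"delta must satisfy 0 < delta <= L0, got {delta_mm}")
    prefix = truncate_by_path_length(traj, L0)
    s = cumulative_arclength(prefix.x, prefix.y)
    targets = np.arange(0.0, L0, delta_mm)
    if L0 - targets[-1] > 1e-9:
        targets = np.append(targets, L0)
    else:
        targets[-1] = L0
    # clip: float rounding can put L0 a hair beyond the last cumulative value
    targets = np.minimum(targets, s[-1])
    px = np.interp(targets, s, prefix.x)
    py = np.interp(targets, s, prefix.y)
    points = np.column_stack([px, py])
    L_delta = float(np.hypot(np.diff(px), np.diff(py)).sum())
    return points, L_delta


def ratio_curve(
    traj: Trajectory, delta_grid: Sequence[float], L0: float = 30.0
) -> CoarseGrainResult:
    """L_delta and L_delta/L_0 across a strictly increasing delta grid."""
    grid = np.asarray(delta_grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ParameterError("delta grid must be nonempty and strictly increasing")
    if grid[0] <= 0 or grid[-1] > L0 + 1e-9:
        raise ParameterError("delta grid values must lie in (0, L0]")
    L = np.array([coarse_grain(traj, d, L0)[1] for d in grid])
    return CoarseGrainResult(
        animal_id=traj.animal_id,
        delta_mm=grid,
        L_delta_mm=L,
        ratio=L / L0,
        L0_mm=L0,
    )


def cohort_log_summary(results: Sequence[CoarseGrainResult]) -> CohortLogSummary:
    """Median and quartiles of log10(ratio) across animals at each delta."""
    if len(results) == 0:
        raise ParameterError("empty cohort")
    grid = results[0].delta_mm
    L0 = results[0].L0_mm
    for r in results[1:]:
        if len(r.delta_mm) != len(grid) or not np.allclose(r.delta_mm, grid):
            mismatched = sorted(set(np.round(r.delta_mm, 9)) ^ set(np.round(grid, 9)))
            raise ParameterError(
                f"delta grids differ between animals (offending values: {mismatched})"
            )
        if abs(r.L0_mm - L0) > 1e-9:
            raise ParameterError("all results must share the same L0")
    logs = np.log10(np.vstack([r.ratio for r in results]))
    q1, med, q3 = np.percentile(logs, [25, 50, 75], axis=0)
    return CohortLogSummary(
        delta_mm=grid,
        median_log10_ratio=med,
        q1_log10_ratio=q1,
        q3_log10_ratio=q3,
        n_animals=len(results),
    )
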