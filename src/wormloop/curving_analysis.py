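"""Signed curving-rate analysis of centroid tracks.

The curving rate is the change in direction of locomotion per unit length
of the animal's advancement, in deg/mm. Curves toward the ventral side are
positive and toward the dorsal side negative whenever the track carries the
animal's ventral orientation; otherwise values stay in the
counter-clockwise-positive mathematical convention and the series is
flagged accordingly.

Two cohort summaries are supported, matching how exploratory assays are
averaged: over a fixed time window (20 minutes of tracking) and over a
fixed advancement distance (the first 30 mm of each track), the latter
making animals of different speeds comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTrackError, ParameterError, WormloopError
from .trajectory_core import Trajectory, truncate_by_path_length
from ._geometry import (
    retain_min_step,
    segment_headings_deg,
    segment_lengths,
    wrap_angle_deg,
)

SignConvention = Literal["ventral_positive", "ccw_positive"]

#: Default minimum advancement between retained samples. Sub-pixel jitter at
#: the 1 s capture interval would otherwise produce unstable headings.
DEFAULT_MIN_STEP_MM = 0.05


@dataclass
class CurvingSeries:
    """Per-step signed curving rates of one track.

    Each entry corresponds to an interior vertex of the minimum-step-filtered
    polyline: the wrapped heading change between the two adjacent steps,
    divided by the mean of their lengths (a centred per-advancement
    estimate). ``step_lengths_mm`` holds those mean adjacent lengths and is
    the weight used by every summary.
    """

    animal_id: str
    step_midpoints_s: np.ndarray
    step_lengths_mm: np.ndarray
    curving_deg_per_mm: np.ndarray
    sign_convention: SignConvention
    t0_s: float = 0.0  # track start; fixed-time windows anchor here

    def __post_init__(self) -> None:
        self.step_midpoints_s = np.asarray(self.step_midpoints_s, dtype=float)
        self.step_lengths_mm = np.asarray(self.step_lengths_mm, dtype=float)
        self.curving_deg_per_mm = np.asarray(self.curving_deg_per_mm, dtype=float)
        if not (
            len(self.step_midpoints_s)
            == len(self.step_lengths_mm)
            == len(self.curving_deg_per_mm)
        ):
            raise ValueError("series arrays must have equal length")
        if np.any(self.step_lengths_mm <= 0):
            raise ValueError("step lengths must be positive")

    def __len__(self) -> int:
        return len(self.curving_deg_per_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "t_mid_s": self.step_midpoints_s,
                "step_mm": self.step_lengths_mm,
                "curving_deg_per_mm": self.curving_deg_per_mm,
                "sign_convention": self.sign_convention,
            }
        )


def compute_curving(traj: Trajectory, min_step_mm: float = DEFAULT_MIN_STEP_MM) -> CurvingSeries:
    """Signed curving-rate series of a trajectory.

    Steps shorter than ``min_step_mm`` are merged into their successors by a
    greedy filter before headings are taken. At each interior retained
    vertex the signed heading change, wrapped to (-180, 180] (exact
    reversals break toward +180), is divided by the mean of the two
    adjacent step lengths.

    Raises
    ------
    DegenerateTrackError
        If fewer than 3 samples survive the minimum-step filter.
    """
    keep = retain_min_step(traj.x, traj.y, min_step_mm)
    if len(keep) < 3:
        raise DegenerateTrackError(
            f"trajectory {traj.animal_id}: only {len(keep)} samples retained "
            f"at min_step {min_step_mm} mm, need >= 3"
        )
    x, y, t = traj.x[keep], traj.y[keep], traj.t[keep]
    headings = segment_headings_deg(x, y)
    lengths = segment_lengths(x, y)
    dh = wrap_angle_deg(np.diff(headings))
    weights = 0.5 * (lengths[:-1] + lengths[1:])
    curving = dh / weights
    convention: SignConvention = "ccw_positive"
    if traj.ventral_is_left is not None:
        convention = "ventral_positive"
        if not traj.ventral_is_left:
            # ventral on the right: a clockwise (negative) turn is ventral-ward
            curving = -curving
    return CurvingSeries(
        animal_id=traj.animal_id,
        step_midpoints_s=t[1:-1],
        step_lengths_mm=weights,
        curving_deg_per_mm=curving,
        sign_convention=convention,
        t0_s=float(traj.t[0]),
    )


def mean_curving(series: CurvingSeries) -> float:
    """Path-length-weighted mean curving rate of a whole series."""
    return float(np.average(series.curving_deg_per_mm, weights=series.step_lengths_mm))


def mean_curving_fixed_time(series: CurvingSeries, window_s: float = 1200.0) -> float:
    """Weighted mean curving over the first ``window_s`` seconds of the track.

    The window is anchored at the track's first sample. Raises if the series
    does not cover the window, reporting the covered duration.
    """
    covered = float(series.step_midpoints_s[-1] - series.t0_s)
    if covered < window_s:
        raise WormloopError(
            f"series covers only {covered:.1f} s, shorter than the "
            f"{window_s:.1f} s window"
        )
    rel = series.step_midpoints_s - series.t0_s
    mask = (rel >= 0) & (rel <= window_s)
    return float(
        np.average(series.curving_deg_per_mm[mask], weights=series.step_lengths_mm[mask])
    )


def mean_curving_fixed_distance(
    traj: Trajectory, L0: float = 30.0, min_step_mm: float = DEFAULT_MIN_STEP_MM
) -> float:
    """Weighted mean curving over the first ``L0`` mm of advancement.

    Equivalent to truncating the track at arc length ``L0`` and averaging
    its full curving series. Propagates a track-too-short error for tracks
    shorter than ``L0``.
    """
    return mean_curving(compute_curving(truncate_by_path_length(traj, L0), min_step_mm))


def total_signed_turning_deg(series: CurvingSeries) -> float:
    """Net signed turning (sum of curving x advancement) in degrees."""
    return float(np.sum(series.curving_deg_per_mm * series.step_lengths_mm))


def curving_histogram(
    series: Sequence[CurvingSeries], bin_width_deg_per_mm: float
) -> pd.DataFrame:
    """Pooled path-length-weighted histogram of curving rates.

    Bins are half-open ``[lo, hi)`` and aligned so 0 deg/mm is a bin edge.
    The summed ``weight_mm`` column equals the pooled analyzed path length
    carried by the series.
    """
    if bin_width_deg_per_mm <= 0:
        raise ParameterError("bin width must be positive")
    if len(series) == 0:
        raise ParameterError("need at least one curving series")
    values = np.concatenate([s.curving_deg_per_mm for s in series])
    weights = np.concatenate([s.step_lengths_mm for s in series])
    w = bin_width_deg_per_mm
    lo = np.floor(values.min() / w) * w
    hi = (np.floor(values.max() / w) + 1) * w  # strictly above max: bins stay half-open
    edges = lo + w * np.arange(round((hi - lo) / w) + 1)
    counts, _ = np.histogram(values, bins=edges, weights=weights)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "weight_mm": counts}
    )
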