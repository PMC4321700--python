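"""Loopy-segment detection and the circular-locomotion (CL) classifier.

A loopy segment is a part of a track forming a closed circle less than
1 cm across. Operationally a candidate closure is a pair of path positions
at least ``min_loop_path_mm`` of arc apart whose spatial separation is at
most ``closure_eps_mm``; the enclosed sub-path counts as a loop when its
minimal enclosing circle is narrower than ``max_loop_diameter_mm`` and its
net signed turning reaches ``min_net_turn_deg``. Overlapping loops merge
into maximal intervals.

An animal shows circular locomotion (CL) when loopy segments cover at
least 30% of its track length; animals moving essentially only in loops
(fraction >= 95% by default, tolerating closure gaps) are classed
"strong", other CL animals "mild", the rest "normal". Assays report the
proportion of CL animals out of the 10 worms scored per plate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import MultiPoint, minimum_bounding_radius

from .errors import DegenerateTrackError, ParameterError
from .trajectory_core import Trajectory
from ._geometry import (
    cumulative_arclength,
    retain_min_step,
    segment_headings_deg,
    wrap_angle_deg,
)
from .curving_analysis import DEFAULT_MIN_STEP_MM


@dataclass
class ClassifierConfig:
    """Thresholds of the loop detector and CL classifier.

    ``max_loop_diameter_mm`` (1 cm) and ``loopy_fraction_threshold`` (30%)
    come from the phenotype definition; the remaining defaults
    operationalise what was originally scored by eye and are configurable.
    """

    max_loop_diameter_mm: float = 10.0
    loopy_fraction_threshold: float = 0.30
    strong_fraction_threshold: float = 0.95
    closure_eps_mm: float = 0.5
    min_loop_path_mm: float = 3.0
    min_net_turn_deg: float = 330.0
    min_step_mm: float = DEFAULT_MIN_STEP_MM

    def __post_init__(self) -> None:
        if not (0 < self.loopy_fraction_threshold < self.strong_fraction_threshold <= 1):
            raise ParameterError(
                "need 0 < loopy_fraction_threshold < strong_fraction_threshold <= 1"
            )
        for name in ("max_loop_diameter_mm", "closure_eps_mm", "min_loop_path_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass
class LoopInterval:
    """One maximal loopy interval in arc-length coordinates."""

    start_mm: float
    end_mm: float
    diameter_mm: float
    net_turn_deg: float

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm


@dataclass
class LoopReport:
    """Loop coverage and CL class of one animal."""

    animal_id: str
    loop_intervals: list[LoopInterval]
    loopy_path_mm: float
    total_path_mm: float
    loopy_fraction: float
    cl_class: str  # strong | mild | normal
    is_cl: bool

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "loopy_fraction": self.loopy_fraction,
            "cl_class": self.cl_class,
            "is_cl": self.is_cl,
            "n_loops": len(self.loop_intervals),
        }


@dataclass
class AssayProportions:
    """Per-assay and pooled percentages of CL animals."""

    per_assay_pct: np.ndarray
    mean_pct: float
    pooled_pct: float
    n_animals: int


def _enclosing_diameter(points: np.ndarray) -> float:
    """Exact minimal-enclosing-circle diameter of a point set."""
    return 2.0 * float(minimum_bounding_radius(MultiPoint(points)))


def _diameter_below(points: np.ndarray, limit: float) -> tuple[bool, float]:
    """Cheap bounding-box screen before the exact enclosing circle.

    The enclosing-circle diameter is at least the larger bbox side and at
    most the bbox diagonal, so most candidates resolve without GEOS.
    """
    span = points.max(axis=0) - points.min(axis=0)
    side = float(span.max())
    if side >= limit:
        return False, side  # lower bound already too wide
    diag = float(np.hypot(*span))
    if diag < limit:
        return True, diag  # upper bound; refined only if the caller needs exactness
    d = _enclosing_diameter(points)
    return d < limit, d


def detect_loops(traj: Trajectory, cfg: ClassifierConfig | None = None) -> list[LoopInterval]:
    """Greedy earliest-closure-first scan for loopy intervals.

    Walks the minimum-step-filtered polyline; at each vertex the earliest
    later vertex that closes (arc separation >= ``min_loop_path_mm``,
    spatial separation <= ``closure_eps_mm``) *and* satisfies the diameter
    and net-turn conditions opens a loop interval, and the scan resumes at
    the closure point. Overlapping or abutting intervals are merged when
    the merged sub-path still fits inside the diameter bound.
    """
    cfg = cfg or ClassifierConfig()
    traj.require_samples(3)
    keep = retain_min_step(traj.x, traj.y, cfg.min_step_mm)
    if len(keep) < 3:
        raise DegenerateTrackError(
            f"trajectory {traj.animal_id}: fewer than 3 samples after min-step filter"
        )
    pts = np.column_stack([traj.x[keep], traj.y[keep]])
    s = cumulative_arclength(pts[:, 0], pts[:, 1])
    headings = segment_headings_deg(pts[:, 0], pts[:, 1])
    # cumulative signed turning at each interior vertex; net turn over
    # vertices i..j is cum[j-1] - cum[i] (O(1) per candidate pair)
    cum = np.concatenate([[0.0], np.cumsum(wrap_angle_deg(np.diff(headings)))])

    def net_turn(i: int, j: int) -> float:
        return cum[j - 1] - cum[i]

    tree = cKDTree(pts)
    raw: list[tuple[int, int]] = []
    i = 0
    n = len(pts)
    while i < n - 1:
        cands = [
            j
            for j in sorted(tree.query_ball_point(pts[i], cfg.closure_eps_mm))
            if j > i and s[j] - s[i] >= cfg.min_loop_path_mm
        ]
        advanced = False
        for j in cands:
            if abs(net_turn(i, j)) < cfg.min_net_turn_deg:
                continue
            ok, _ = _diameter_below(pts[i : j + 1], cfg.max_loop_diameter_mm)
            if ok:
                raw.append((i, j))
                i = j
                advanced = True
                break
        if not advanced:
            i += 1

    # merge overlapping/abutting intervals while the diameter bound holds
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            pa, pb = merged[-1]
            ok, _ = _diameter_below(pts[pa : b + 1], cfg.max_loop_diameter_mm)
            if ok:
                merged[-1] = (pa, b)
                continue
        merged.append((a, b))

    out = []
    for a, b in merged:
        diam = _enclosing_diameter(pts[a : b + 1])
        out.append(
            LoopInterval(
                start_mm=float(s[a]),
                end_mm=float(s[b]),
                diameter_mm=diam,
                net_turn_deg=float(net_turn(a, b)),
            )
        )
    return out


def classify_cl(traj: Trajectory, cfg: ClassifierConfig | None = None) -> LoopReport:
    """Classify one animal as strong / mild / normal from its loop coverage."""
    cfg = cfg or ClassifierConfig()
    intervals = detect_loops(traj, cfg)
    keep = retain_min_step(traj.x, traj.y, cfg.min_step_mm)
    total = float(
        cumulative_arclength(traj.x[keep], traj.y[keep])[-1]
    )
    loopy = float(sum(iv.length_mm for iv in intervals))
    fraction = loopy / total if total > 0 else 0.0
    if fraction >= cfg.strong_fraction_threshold:
        cl_class = "strong"
    elif fraction >= cfg.loopy_fraction_threshold:
        cl_class = "mild"
    else:
        cl_class = "normal"
    return LoopReport(
        animal_id=traj.animal_id,
        loop_intervals=intervals,
        loopy_path_mm=loopy,
        total_path_mm=total,
        loopy_fraction=fraction,
        cl_class=cl_class,
        is_cl=cl_class in ("strong", "mild"),
    )


def assay_cl_proportion(
    reports: Sequence[LoopReport],
    worms_per_assay: int = 10,
    allow_partial_last: bool = False,
) -> AssayProportions:
    """Percent of CL animals per assay plate plus mean and pooled percentages.

    Reports are grouped in input order into assays of ``worms_per_assay``
    animals (10 worms scored per plate by default). A short final group is
    an error unless ``allow_partial_last`` is set.
    """
    if len(reports) == 0:
        raise ParameterError("no reports supplied")
    if worms_per_assay < 1:
        raise ParameterError("worms_per_assay must be >= 1")
    if len(reports) % worms_per_assay != 0 and not allow_partial_last:
        raise ParameterError(
            f"{len(reports)} reports do not divide into assays of {worms_per_assay}"
        )
    flags = np.array([r.is_cl for r in reports], dtype=bool)
    groups = [
        flags[k : k + worms_per_assay] for k in range(0, len(flags), worms_per_assay)
    ]
    per_assay = np.array([100.0 * g.mean() for g in groups])
    return AssayProportions(
        per_assay_pct=per_assay,
        mean_pct=float(per_assay.mean()),
        pooled_pct=float(100.0 * flags.mean()),
        n_animals=len(flags),
    )


def reports_to_frame(reports: Sequence[LoopReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
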