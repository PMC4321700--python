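"""Trajectory and head-pose data model, delimited-text I/O, and preprocessing.

The unit of all path analyses is a :class:`Trajectory`: the time-ordered
centroid positions of one animal recorded by a multi-worm tracker at a
nominal 1,000 ms capture interval, in planar millimetres. Whether the
animal's ventral side lies to the left of its heading is carried as
tri-state metadata (``True`` / ``False`` / ``None`` for unknown); signed
quantities downstream are reported ventral-positive when it is known and in
the counter-clockwise-positive mathematical convention otherwise.

Tracks of animals that crossed each other are excluded from analysis; here
that is an ``excluded`` flag set by :func:`flag_crossings` rather than a
hard deletion, so the decision is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTrackError,
    FormatError,
    ParseError,
    TrackTooShortError,
)
from ._geometry import cumulative_arclength, segment_lengths

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ("animal_id", "t_s", "x_mm", "y_mm")
POSE_COLUMNS = ("animal_id", "t_s", "cx", "cy", "bx", "by", "nx", "ny")

_VENTRAL_TRUE = {"true", "1", "yes", "left"}
_VENTRAL_FALSE = {"false", "0", "no", "right"}
_VENTRAL_UNKNOWN = {"", "unknown", "na", "nan", "none"}


@dataclass
class AssayConfig:
    """Geometry and timing of an exploratory-behavior assay.

    ``fixed_distance_mm`` is the L0 of the fixed-distance analyses: the
    curving rate and coarse-grained statistics are computed over the first
    30 mm of each track so that animals moving at different speeds are
    comparable.
    """

    plate_diameter_mm: float = 90.0
    assay_duration_s: float = 3600.0
    worms_per_assay: int = 10
    fixed_time_window_s: float = 1200.0
    fixed_distance_mm: float = 30.0
    nominal_interval_s: float = 1.0
    interval_tolerance_s: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "plate_diameter_mm",
            "assay_duration_s",
            "worms_per_assay",
            "fixed_time_window_s",
            "fixed_distance_mm",
            "nominal_interval_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Time-ordered centroid track of a single animal.

    Parameters
    ----------
    animal_id : str
        Label of the animal (tracker blob id or simulation label).
    t : ndarray
        Sample times in seconds, strictly increasing.
    x, y : ndarray
        Centroid coordinates in millimetres.
    ventral_is_left : bool or None
        Whether the ventral side lies to the left of the heading; ``None``
        when the anatomical orientation was not recorded.
    excluded : bool
        Set when the track was contaminated by a crossing with another
        animal and must not enter cohort statistics.
    """

    animal_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ventral_is_left: Optional[bool] = None
    excluded: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite time values")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite coordinates")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def path_length(self) -> float:
        """Total polyline length in millimetres."""
        return float(segment_lengths(self.x, self.y).sum())

    def net_displacement(self) -> float:
        """Straight-line distance from first to last sample."""
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    def check_sampling(self, config: AssayConfig | None = None) -> int:
        """Log intervals deviating from the nominal capture rate; return their count."""
        cfg = config or AssayConfig()
        dt = np.diff(self.t)
        bad = np.abs(dt - cfg.nominal_interval_s) > cfg.interval_tolerance_s
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning(
                "trajectory %s: %d of %d intervals deviate from the nominal %.3g s",
                self.animal_id, n_bad, len(dt), cfg.nominal_interval_s,
            )
        return n_bad

    def require_samples(self, n: int = 3) -> None:
        if len(self) < n:
            raise DegenerateTrackError(
                f"trajectory {self.animal_id}: {len(self)} samples, need >= {n}"
            )


@dataclass
class HeadPoseSeries:
    """Per-frame head landmarks (centroid, pharynx terminal bulb, nose tip).

    Frames are nominally 0.5 s apart; actual timestamps are kept as recorded.
    """

    animal_id: str
    t: np.ndarray
    centroid: np.ndarray      # (n, 2) mm
    terminal_bulb: np.ndarray  # (n, 2) mm
    nose_tip: np.ndarray       # (n, 2) mm
    ventral_is_left: Optional[bool] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(-1, 2)
        self.terminal_bulb = np.asarray(self.terminal_bulb, dtype=float).reshape(-1, 2)
        self.nose_tip = np.asarray(self.nose_tip, dtype=float).reshape(-1, 2)
        n = len(self.t)
        if not (len(self.centroid) == len(self.terminal_bulb) == len(self.nose_tip) == n):
            raise ValueError("landmark arrays must match t in length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def _parse_ventral(value: object) -> Optional[bool]:
    s = str(value).strip().lower()
    if s in _VENTRAL_TRUE:
        return True
    if s in _VENTRAL_FALSE:
        return False
    if s in _VENTRAL_UNKNOWN:
        return None
    raise ValueError(f"unrecognised ventral_is_left value: {value!r}")


def _numeric_column(df: pd.DataFrame, col: str) -> np.ndarray:
    """Convert a column to float, reporting the 1-based file line of a bad value."""
    raw = df[col]
    bad = pd.to_numeric(raw, errors="coerce").isna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header occupies line 1, data starts at line 2
        raise ParseError(
            f"non-numeric value {raw.iloc[idx]!r} in column '{col}' at line {idx + 2}",
            line_number=idx + 2,
        )
    # astype parses with the exact strtod (to_numeric's fast path loses ulps)
    return raw.astype(float).to_numpy()


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    # keep_default_na=False so literal "NA" in numeric columns is caught as a
    # parse error with a line number instead of silently becoming missing
    # dtype=str: numeric conversion is done per-column below with the exact
    # strtod; keep_default_na=False so literal "NA" is a parse error, not missing
    df = pd.read_csv(path, sep=None, engine="python", keep_default_na=False, dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    return df


def read_trajectories(path, config: AssayConfig | None = None) -> list[Trajectory]:
    """Read a tracker-style delimited file into one :class:`Trajectory` per animal.

    Comma or tab delimiters are auto-detected. Required columns:
    ``animal_id,t_s,x_mm,y_mm``; ``ventral_is_left`` is optional and
    preserved as unknown when absent. Samples are sorted by time within
    each animal; duplicate timestamps keep the first sample and log the rest.
    """
    df = _read_table(path, TRAJECTORY_COLUMNS)
    t_all = _numeric_column(df, "t_s")
    x_all = _numeric_column(df, "x_mm")
    y_all = _numeric_column(df, "y_mm")
    has_ventral = "ventral_is_left" in df.columns

    trajectories: list[Trajectory] = []
    ids = df["animal_id"].astype(str).to_numpy()
    for animal in pd.unique(ids):
        sel = np.flatnonzero(ids == animal)
        order = sel[np.argsort(t_all[sel], kind="stable")]
        t, x, y = t_all[order], x_all[order], y_all[order]
        keep = np.concatenate([[True], np.diff(t) > 0])
        if not keep.all():
            logger.warning(
                "animal %s: dropped %d duplicate timestamp(s), kept first",
                animal, int((~keep).sum()),
            )
            t, x, y = t[keep], x[keep], y[keep]
        ventral = None
        if has_ventral:
            ventral = _parse_ventral(df["ventral_is_left"].iloc[order[0]])
        traj = Trajectory(str(animal), t, x, y, ventral_is_left=ventral)
        if config is not None:
            traj.check_sampling(config)
        trajectories.append(traj)
    return trajectories


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories in the same format :func:`read_trajectories` accepts.

    Floats are written at full round-trip precision.
    """
    frames = []
    for traj in trajectories:
        ventral = "" if traj.ventral_is_left is None else str(traj.ventral_is_left).lower()
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": traj.animal_id,
                    "t_s": traj.t,
                    "x_mm": traj.x,
                    "y_mm": traj.y,
                    "ventral_is_left": ventral,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_head_poses(path) -> list[HeadPoseSeries]:
    """Read head-landmark tables: ``animal_id,t_s,cx,cy,bx,by,nx,ny[,ventral_is_left]``."""
    df = _read_table(path, POSE_COLUMNS)
    cols = {c: _numeric_column(df, c) for c in POSE_COLUMNS[1:]}
    has_ventral = "ventral_is_left" in df.columns
    ids = df["animal_id"].astype(str).to_numpy()
    out = []
    for animal in pd.unique(ids):
        sel = np.flatnonzero(ids == animal)
        order = sel[np.argsort(cols["t_s"][sel], kind="stable")]
        ventral = _parse_ventral(df["ventral_is_left"].iloc[order[0]]) if has_ventral else None
        out.append(
            HeadPoseSeries(
                str(animal),
                cols["t_s"][order],
                np.column_stack([cols["cx"][order], cols["cy"][order]]),
                np.column_stack([cols["bx"][order], cols["by"][order]]),
                np.column_stack([cols["nx"][order], cols["ny"][order]]),
                ventral_is_left=ventral,
            )
        )
    return out


def flag_crossings(
    trajectories: Sequence[Trajectory], min_separation_mm: float = 1.0
) -> list[Trajectory]:
    """Mark every pair of tracks that came within one body width as excluded.

    For each pair with overlapping time coverage, both tracks are linearly
    interpolated onto the union of their sample times inside the overlap; if
    the minimum centroid separation falls below ``min_separation_mm``
    (default 1 mm, roughly one adult body width) both members are flagged
    ``excluded=True``. Order is preserved and inputs are not mutated.
    """
    n = len(trajectories)
    flagged = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            a, b = trajectories[i], trajectories[j]
            lo = max(a.t[0], b.t[0])
            hi = min(a.t[-1], b.t[-1])
            if lo > hi:
                continue
            times = np.union1d(
                a.t[(a.t >= lo) & (a.t <= hi)], b.t[(b.t >= lo) & (b.t <= hi)]
            )
            if len(times) == 0:
                continue
            ax, ay = np.interp(times, a.t, a.x), np.interp(times, a.t, a.y)
            bx, by = np.interp(times, b.t, b.x), np.interp(times, b.t, b.y)
            if np.min(np.hypot(ax - bx, ay - by)) < min_separation_mm:
                flagged[i] = flagged[j] = True
    return [
        dataclasses.replace(traj, excluded=True) if hit and not traj.excluded else traj
        for traj, hit in zip(trajectories, flagged)
    ]


def truncate_by_path_length(traj: Trajectory, L0: float) -> Trajectory:
    """Return the prefix of the track whose path length equals ``L0``.

    The final point is linearly interpolated along the last segment so the
    returned path length matches ``L0`` exactly (up to float rounding); its
    timestamp is interpolated the same way. Used for the fixed-distance
    (first 30 mm) analyses.
    """
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    s = cumulative_arclength(traj.x, traj.y)
    total = s[-1]
    if total < L0 - 1e-9:
        raise TrackTooShortError(
            f"trajectory {traj.animal_id}: path length {total:.4f} mm < L0 = {L0} mm",
            actual_length_mm=total,
        )
    if abs(total - L0) <= 1e-9:
        return dataclasses.replace(traj)
    k = int(np.searchsorted(s, L0, side="left"))  # first vertex with s >= L0
    if abs(s[k] - L0) <= 1e-12:
        return dataclasses.replace(
            traj, t=traj.t[: k + 1].copy(), x=traj.x[: k + 1].copy(), y=traj.y[: k + 1].copy()
        )
    frac = (L0 - s[k - 1]) / (s[k] - s[k - 1])
    xe = traj.x[k - 1] + frac * (traj.x[k] - traj.x[k - 1])
    ye = traj.y[k - 1] + frac * (traj.y[k] - traj.y[k - 1])
    te = traj.t[k - 1] + frac * (traj.t[k] - traj.t[k - 1])
    return dataclasses.replace(
        traj,
        t=np.append(traj.t[:k], te),
        x=np.append(traj.x[:k], xe),
        y=np.append(traj.y[:k], ye),
    )
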