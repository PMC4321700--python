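"""Head-angle kinematics of foraging behavior.

The head angle of a frame is the angle between the line from the worm
centroid to the pharynx terminal bulb and the line from the terminal bulb
to the nose tip, sampled every 500 ms. Ventral bends count positive,
dorsal bends negative; when the ventral side is unknown the series stays
in the counter-clockwise-positive convention.

Bends are prominent local extrema of the head-angle trace; ventral and
dorsal bend angles are summarized separately (the dorsal mean is reported
both signed and as a magnitude, since either reading may be wanted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DegeneratePoseError
from .trajectory_core import HeadPoseSeries

logger = logging.getLogger(__name__)

SignConvention = Literal["ventral_positive", "ccw_positive"]

#: Landmarks closer than this are considered coincident (degenerate pose).
DEFAULT_EPS_LANDMARK_MM = 1e-6

#: Default prominence for a local extremum to count as a bend.
DEFAULT_PROMINENCE_DEG = 10.0


@dataclass
class HeadAngleSeries:
    animal_id: str
    t: np.ndarray
    angle_deg: np.ndarray
    sign_convention: SignConvention

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if len(self.t) != len(self.angle_deg):
            raise ValueError("t and angle_deg must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "angle_deg": self.angle_deg})


@dataclass
class BendSummary:
    """Ventral and dorsal bend angles extracted from one head-angle trace."""

    ventral_bend_angles_deg: np.ndarray
    dorsal_bend_angles_deg: np.ndarray
    mean_ventral_deg: float
    mean_dorsal_deg: float          # signed (negative)
    mean_dorsal_magnitude_deg: float
    n_ventral: int
    n_dorsal: int


def head_angle(
    centroid, terminal_bulb, nose_tip,
    ventral_is_left: Optional[bool] = None,
    eps_landmark_mm: float = DEFAULT_EPS_LANDMARK_MM,
) -> float:
    """Signed head angle of a single frame, degrees in (-180, 180].

    The unsigned part is the angle between the centroid->bulb and
    bulb->nose vectors; the sign comes from their cross product
    (counter-clockwise positive) remapped so ventral is positive when the
    ventral side is known. Invariant under rigid motions and uniform
    scaling of the landmark triple.
    """
    c = np.asarray(centroid, dtype=float)
    b = np.asarray(terminal_bulb, dtype=float)
    n = np.asarray(nose_tip, dtype=float)
    v1 = b - c
    v2 = n - b
    if (
        np.hypot(*v1) <= eps_landmark_mm
        or np.hypot(*v2) <= eps_landmark_mm
        or np.hypot(*(n - c)) <= eps_landmark_mm
    ):
        raise DegeneratePoseError("coincident landmarks; head angle undefined")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1 @ v2
    angle = math.degrees(math.atan2(cross, dot))
    if angle == -180.0:  # tie-break exact reversals toward +180
        angle = 180.0
    if ventral_is_left is False:
        angle = -angle
    return angle


def head_angle_series(
    poses: HeadPoseSeries, eps_landmark_mm: float = DEFAULT_EPS_LANDMARK_MM
) -> HeadAngleSeries:
    """Per-frame head angles; degenerate frames are dropped and logged."""
    if len(poses) < 2:
        raise ValueError("need at least 2 frames")
    t_out, a_out = [], []
    n_dropped = 0
    for k in range(len(poses)):
        try:
            a = head_angle(
                poses.centroid[k],
                poses.terminal_bulb[k],
                poses.nose_tip[k],
                ventral_is_left=poses.ventral_is_left,
                eps_landmark_mm=eps_landmark_mm,
            )
        except DegeneratePoseError:
            n_dropped += 1
            continue
        t_out.append(poses.t[k])
        a_out.append(a)
    if n_dropped:
        logger.warning(
            "pose series %s: dropped %d degenerate frame(s)", poses.animal_id, n_dropped
        )
    convention: SignConvention = (
        "ventral_positive" if poses.ventral_is_left is not None else "ccw_positive"
    )
    return HeadAngleSeries(
        animal_id=poses.animal_id,
        t=np.array(t_out),
        angle_deg=np.array(a_out),
        sign_convention=convention,
    )


def extract_bends(
    series: HeadAngleSeries, prominence_deg: float = DEFAULT_PROMINENCE_DEG
) -> BendSummary:
    """Bend angles as prominent local extrema of the head-angle trace.

    Positive extrema feed the ventral list, negative extrema the dorsal
    list. A trace with no qualifying extrema yields an empty summary with
    zero counts (NaN means), not an error.
    """
    a = series.angle_deg
    if len(a) < 3:
        return BendSummary(np.array([]), np.array([]), math.nan, math.nan, math.nan, 0, 0)
    peaks, _ = find_peaks(a, prominence=prominence_deg)
    troughs, _ = find_peaks(-a, prominence=prominence_deg)
    ventral = a[peaks][a[peaks] > 0]
    dorsal = a[troughs][a[troughs] < 0]
    return BendSummary(
        ventral_bend_angles_deg=ventral,
        dorsal_bend_angles_deg=dorsal,
        mean_ventral_deg=float(ventral.mean()) if len(ventral) else math.nan,
        mean_dorsal_deg=float(dorsal.mean()) if len(dorsal) else math.nan,
        mean_dorsal_magnitude_deg=float(-dorsal.mean()) if len(dorsal) else math.nan,
        n_ventral=int(len(ventral)),
        n_dorsal=int(len(dorsal)),
    )
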