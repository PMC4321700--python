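"""Planar geometry helpers shared by the path-analysis modules.

All angles are degrees, all lengths millimetres. The mathematical sign
convention is counter-clockwise positive; modules that know the animal's
ventral side remap to ventral-positive on top of this.
"""

from __future__ import annotations

import numpy as np


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angular difference(s) into (-180, 180].

    Exact reversals (odd multiples of 180) map to +180 so that the
    tie-break is deterministic.
    """
    return -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)


def segment_headings_deg(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heading of each polyline segment, degrees in (-180, 180]."""
    return np.degrees(np.arctan2(np.diff(y), np.diff(x)))


def segment_lengths(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.hypot(np.diff(x), np.diff(y))


def cumulative_arclength(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Arc length at each vertex, starting at 0."""
    out = np.empty(len(x))
    out[0] = 0.0
    np.cumsum(segment_lengths(x, y), out=out[1:])
    return out


def retain_min_step(x: np.ndarray, y: np.ndarray, min_step_mm: float) -> np.ndarray:
    """Indices of vertices kept by the greedy minimum-step filter.

    The first vertex is always kept; each subsequent vertex is kept only if
    its distance from the previously kept vertex is at least ``min_step_mm``.
    Removes sub-pixel tracker jitter that would destabilise headings.
    """
    keep = [0]
    last = 0
    for k in range(1, len(x)):
        if np.hypot(x[k] - x[last], y[k] - y[last]) >= min_step_mm:
            keep.append(k)
            last = k
    return np.asarray(keep, dtype=np.intp)


def interp_along_path(
    x: np.ndarray, y: np.ndarray, arc_targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Points at the given arc-length positions, linearly interpolated on the polyline."""
    s = cumulative_arclength(x, y)
    return np.interp(arc_targets, s, x), np.interp(arc_targets, s, y)
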