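import numpy as np
import pytest

from wormloop import Trajectory


def make_circle_track(
    radius_mm: float,
    arc_step_mm: float,
    total_arc_mm: float,
    ccw: bool = True,
    animal_id: str = "circle",
    ventral_is_left=True,
    start_angle_rad: float = 0.0,
    center=(0.0, 0.0),
) -> Trajectory:
    """Parametric circle sampled at constant arc steps (analytic oracle input)."""
    n = int(round(total_arc_mm / arc_step_mm))
    dth = arc_step_mm / radius_mm * (1 if ccw else -1)
    th = start_angle_rad + dth * np.arange(n + 1)
    x = center[0] + radius_mm * np.cos(th)
    y = center[1] + radius_mm * np.sin(th)
    return Trajectory(
        animal_id, np.arange(n + 1, dtype=float), x, y, ventral_is_left=ventral_is_left
    )


def make_straight_track(
    length_mm: float, step_mm: float = 1.0, animal_id: str = "straight", ventral_is_left=True
) -> Trajectory:
    n = int(round(length_mm / step_mm))
    x = step_mm * np.arange(n + 1)
    return Trajectory(
        animal_id,
        np.arange(n + 1, dtype=float),
        x,
        np.zeros(n + 1),
        ventral_is_left=ventral_is_left,
    )


@pytest.fixture
def circle_track():
    return make_circle_track


@pytest.fixture
def straight_track():
    return make_straight_track
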