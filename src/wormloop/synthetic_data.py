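"""Synthetic generators with the statistical structure the analyses assume.

Trajectories come from a correlated random walk: the heading turns each
step by (regime curving bias + Gaussian noise) x the step's advancement,
so the bias is a curving rate in deg/mm — matching the per-unit-length
definition used by the analysis — and position advances at constant speed.
A two-state Markov regime ("normal" vs "loopy") produces bouts of strong
curving like those of Ras-pathway mutants; a constant-bias noise-free walk
closes onto a circle of diameter 360/(pi * |bias|) mm.

Head-pose series realize a programmed asymmetric head-angle oscillation
through landmark geometry chosen so the head-angle computation inverts it
exactly. Fluorescence records emulate bleach-and-recovery triples with
50-70% post-bleach retention.

All generators are pure functions of their config (seed included):
identical configs give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError
from .trajectory_core import HeadPoseSeries, Trajectory
from .fluorescence_quant import FluorescenceRecord


@dataclass
class WalkConfig:
    """Correlated-random-walk parameters for one simulated animal.

    ``bias_deg_per_mm`` is the mean curving rate in the normal regime
    (positive = ventral-ward); ``loopy_bias_deg_per_mm`` applies inside
    loopy bouts. Each step the regime toggles with probability
    ``bout_switch_prob``. Speed defaults to 0.15 mm/s at the tracker's
    1 s capture interval.
    """

    speed_mm_per_s: float = 0.15
    step_s: float = 1.0
    bias_deg_per_mm: float = 0.0
    noise_deg_per_mm_sd: float = 0.0
    bout_switch_prob: float = 0.0
    loopy_bias_deg_per_mm: float = 0.0
    start_regime: Literal["normal", "loopy"] = "normal"
    duration_s: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bout_switch_prob <= 1.0):
            raise ParameterError("bout_switch_prob must be in [0, 1]")
        if self.speed_mm_per_s <= 0 or self.step_s <= 0 or self.duration_s <= 0:
            raise ParameterError("speed, step and duration must be positive")
        if self.noise_deg_per_mm_sd < 0:
            raise ParameterError("noise sd must be nonnegative")
        if self.start_regime not in ("normal", "loopy"):
            raise ParameterError("start_regime must be 'normal' or 'loopy'")


@dataclass
class HeadWaveConfig:
    """Asymmetric head-angle oscillation: positive half-cycles scaled to the
    ventral amplitude, negative half-cycles to the dorsal amplitude."""

    ventral_amp_deg: float = 30.0
    dorsal_amp_deg: float = 30.0
    period_s: float = 4.0
    noise_deg_sd: float = 0.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ventral_amp_deg <= 0 or self.dorsal_amp_deg <= 0:
            raise ParameterError("amplitudes must be positive")
        if self.period_s <= 2 * 0.5:
            raise ParameterError("period must exceed twice the 0.5 s sampling interval")
        if self.noise_deg_sd < 0:
            raise ParameterError("noise sd must be nonnegative")


@dataclass
class FluorSimConfig:
    """Bleach-and-recovery intensity triples.

    Post-bleach intensity retains a uniform draw from
    ``bleach_retention_range`` (default 50-70%) of the intact signal;
    the post-treatment intensity recovers ``recovery_fraction`` of what
    bleaching removed. ``background_level`` is added to every ROI value
    and reported at the three background points, so the analysis must
    background-correct to recover the programmed fractions.
    """

    intact_mean: float = 100.0
    bleach_retention_range: tuple[float, float] = (0.5, 0.7)
    recovery_fraction: float = 1.0
    noise_sd: float = 0.0
    background_level: float = 10.0
    n_animals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bleach_retention_range
        if not (0.0 < lo <= hi < 1.0):
            raise ParameterError("bleach_retention_range must lie within (0, 1)")
        if not (0.0 <= self.recovery_fraction <= 1.0):
            raise ParameterError("recovery_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be nonnegative")
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")


def simulate_trajectory(cfg: WalkConfig, animal_id: str = "sim") -> Trajectory:
    """Simulate one correlated-random-walk trajectory.

    The ventral side is set to the left of the heading, so a positive bias
    produces ventral-ward curving under the analysis sign convention.
    """
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.duration_s / cfg.step_s))
    if n_steps < 2:
        raise ParameterError("duration too short for the step size")
    ds = cfg.speed_mm_per_s * cfg.step_s

    toggles = rng.random(n_steps) < cfg.bout_switch_prob
    start_loopy = cfg.start_regime == "loopy"
    loopy = np.logical_xor(np.cumsum(toggles) % 2 == 1, start_loopy)
    # regime in effect during step k is the state after that step's toggle draw
    rates = np.where(loopy, cfg.loopy_bias_deg_per_mm, cfg.bias_deg_per_mm)
    noise = rng.standard_normal(n_steps) * cfg.noise_deg_per_mm_sd
    turns_deg = (rates + noise) * ds
    headings = np.radians(np.cumsum(turns_deg))

    x = np.concatenate([[0.0], np.cumsum(ds * np.cos(headings))])
    y = np.concatenate([[0.0], np.cumsum(ds * np.sin(headings))])
    t = cfg.step_s * np.arange(n_steps + 1)
    return Trajectory(animal_id, t, x, y, ventral_is_left=True)


def circle_diameter_mm(bias_deg_per_mm: float) -> float:
    """Diameter of the circle a constant-bias noise-free walk closes onto."""
    if bias_deg_per_mm == 0:
        raise ParameterError("zero bias never closes")
    return 360.0 / (np.pi * abs(bias_deg_per_mm))


def simulate_cohort(
    cfg_wt: WalkConfig,
    cfg_mut: WalkConfig,
    n_per_group: int,
    seed: int,
) -> list[tuple[str, Trajectory]]:
    """Simulate labelled wild-type-like and mutant-like cohorts.

    Per-animal seeds are derived deterministically from the master seed;
    the per-animal configs are the group configs with only the seed (and
    animal id) replaced.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_group)
    out: list[tuple[str, Trajectory]] = []
    for k in range(n_per_group):
        cfg = dataclasses.replace(cfg_wt, seed=int(seeds[k]))
        out.append(("wt", simulate_trajectory(cfg, animal_id=f"wt_{k:03d}")))
    for k in range(n_per_group):
        cfg = dataclasses.replace(cfg_mut, seed=int(seeds[n_per_group + k]))
        out.append(("mutant", simulate_trajectory(cfg, animal_id=f"mut_{k:03d}")))
    return out


def programmed_head_angles(cfg: HeadWaveConfig) -> tuple[np.ndarray, np.ndarray]:
    """Timestamps and noise-free programmed head angles of a head wave."""
    t = 0.5 * np.arange(int(np.floor(cfg.duration_s / 0.5)) + 1)
    s = np.sin(2 * np.pi * t / cfg.period_s)
    angles = np.where(s >= 0, cfg.ventral_amp_deg * s, cfg.dorsal_amp_deg * s)
    return t, angles


def simulate_head_wave(
    cfg: HeadWaveConfig, animal_id: str = "sim"
) -> tuple[HeadPoseSeries, np.ndarray]:
    """Simulate a head-pose series realizing an asymmetric head oscillation.

    Landmark geometry: centroid at the origin, terminal bulb 1 mm along
    the body axis (+x), nose tip 0.5 mm from the bulb rotated by the
    programmed angle — so the head-angle computation recovers the
    programmed angles exactly in the noise-free case (ventral side on the
    left, making counter-clockwise = ventral-positive).

    Returns the pose series and the realized (noise-included) angles.
    """
    rng = np.random.default_rng(cfg.seed)
    t, angles = programmed_head_angles(cfg)
    if cfg.noise_deg_sd > 0:
        angles = angles + rng.standard_normal(len(t)) * cfg.noise_deg_sd
    n = len(t)
    centroid = np.zeros((n, 2))
    bulb = np.tile([1.0, 0.0], (n, 1))
    rad = np.radians(angles)
    nose = bulb + 0.5 * np.column_stack([np.cos(rad), np.sin(rad)])
    poses = HeadPoseSeries(
        animal_id, t, centroid, bulb, nose, ventral_is_left=True
    )
    return poses, angles


def simulate_fluorescence(
    cfg: FluorSimConfig, condition: str = "heat_shock"
) -> list[FluorescenceRecord]:
    """Simulate bleach-and-recovery records for one treatment group.

    Per animal: intact ~ intact_mean + noise; post-bleach = intact x a
    uniform retention draw; post-treatment = post-bleach +
    recovery_fraction x (intact - post-bleach) + noise. The background
    level is added to every ROI value and reported at the background
    points, noisy when ``noise_sd`` > 0.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bleach_retention_range
    records = []
    for k in range(cfg.n_animals):
        intact = cfg.intact_mean + rng.standard_normal() * cfg.noise_sd
        retention = rng.uniform(lo, hi)
        bleached = intact * retention
        after = bleached + cfg.recovery_fraction * (intact - bleached)
        after += rng.standard_normal() * cfg.noise_sd
        bgs = cfg.background_level + rng.standard_normal((3, 3)) * cfg.noise_sd
        records.append(
            FluorescenceRecord(
                animal_id=f"{condition}_{k:03d}",
                roi_intact=intact + bgs[0].mean(),
                roi_bleached=bleached + bgs[1].mean(),
                roi_after=after + bgs[2].mean(),
                bg_intact=tuple(bgs[0]),
                bg_bleached=tuple(bgs[1]),
                bg_after=tuple(bgs[2]),
                condition=condition,
            )
        )
    return records
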