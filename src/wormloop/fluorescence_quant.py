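"""GFP-knockdown fluorescence quantification.

Each animal is imaged three times at fixed excitation: intact (before
photobleaching), just after photobleaching, and after the treatment
(heat shock plus recovery, or a mock/control incubation). Photobleaching
is expected to leave 50-70% of the intact intensity. All ROI means are
background-corrected by subtracting the average of three random background
points before any ratio is formed — the only ordering that removes a
camera offset from every term.

rate of change = (after - bleached) / (intact - bleached), so 0 means no
recovery of fluorescence and 1 full recovery. The per-animal recovery
ratio normalizes against the control group:
rate_of_change(animal) - mean(control rates) + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientBleachError, ParameterError

logger = logging.getLogger(__name__)

#: Denominator guard for the rate-of-change formula, as a fraction of the
#: corrected intact intensity.
BLEACH_EPS_FRACTION = 0.01

#: Expected corrected bleached/intact ratio; outside this range a warning
#: is logged but the record remains usable.
EXPECTED_RETENTION = (0.5, 0.7)


def background_correct(roi_value: float, bg_points: Sequence[float]) -> float:
    """ROI intensity minus the mean of exactly three background points.

    The result may be negative (flagged by callers); clipping is left to
    operations that require nonnegative intensities.
    """
    bg = np.asarray(bg_points, dtype=float)
    if bg.shape != (3,):
        raise FormatError(f"expected exactly 3 background points, got {bg.size}")
    return float(roi_value - bg.mean())


@dataclass
class FluorescenceRecord:
    """Intact / post-bleach / post-treatment ROI means of one animal."""

    animal_id: str
    roi_intact: float
    roi_bleached: float
    roi_after: float
    bg_intact: tuple[float, float, float]
    bg_bleached: tuple[float, float, float]
    bg_after: tuple[float, float, float]
    condition: str = "heat_shock"  # heat_shock | control

    def __post_init__(self) -> None:
        if self.condition not in ("heat_shock", "control"):
            raise ParameterError(f"unknown condition {self.condition!r}")

    @property
    def corrected_intact(self) -> float:
        return background_correct(self.roi_intact, self.bg_intact)

    @property
    def corrected_bleached(self) -> float:
        return background_correct(self.roi_bleached, self.bg_bleached)

    @property
    def corrected_after(self) -> float:
        return background_correct(self.roi_after, self.bg_after)

    @property
    def retention(self) -> float:
        """Corrected bleached/intact ratio; photobleaching should leave 0.5-0.7."""
        return self.corrected_bleached / self.corrected_intact

    @property
    def is_valid(self) -> bool:
        """Photobleaching must actually have reduced the corrected intensity."""
        return self.corrected_intact > self.corrected_bleached

    def check(self) -> None:
        if not self.is_valid:
            logger.warning(
                "record %s: corrected intact <= corrected bleached; invalid",
                self.animal_id,
            )
        elif not (EXPECTED_RETENTION[0] <= self.retention <= EXPECTED_RETENTION[1]):
            logger.warning(
                "record %s: bleach retention %.3f outside the expected %s range",
                self.animal_id, self.retention, EXPECTED_RETENTION,
            )


def rate_of_change(
    rec: FluorescenceRecord, eps_fraction: float = BLEACH_EPS_FRACTION
) -> float:
    """(after - bleached) / (intact - bleached) on background-corrected values.

    0 = no recovery, 1 = full recovery; values outside [0, 1] are allowed
    (over-recovery or continued loss) and logged. Raises when bleaching
    removed less than ``eps_fraction`` of the corrected intact intensity.
    """
    ci = rec.corrected_intact
    cb = rec.corrected_bleached
    ca = rec.corrected_after
    denom = ci - cb
    if denom <= eps_fraction * abs(ci):
        raise InsufficientBleachError(
            f"record {rec.animal_id}: intact - bleached = {denom:.4g}, "
            "too small for the rate-of-change formula"
        )
    value = (ca - cb) / denom
    if not (0.0 <= value <= 1.0):
        logger.warning("record %s: rate of change %.3f outside [0, 1]", rec.animal_id, value)
    return float(value)


@dataclass
class RecoveryResult:
    """Per-animal recovery ratios of a heat-shock group against controls."""

    animal_ids: list[str]
    ratios: np.ndarray
    mean: float
    sd: float
    control_mean_rate: float
    n_heat_shock: int
    n_control: int


def recovery_ratio(
    heat_shock_records: Sequence[FluorescenceRecord],
    control_records: Sequence[FluorescenceRecord],
) -> RecoveryResult:
    """Control-normalized recovery ratio per heat-shocked animal.

    ratio = rate_of_change(animal) - mean(control rates of change) + 1.
    Control rates are averaged after background correction.
    """
    if len(control_records) == 0:
        raise ParameterError("control group is empty")
    if len(heat_shock_records) == 0:
        raise ParameterError("heat-shock group is empty")
    control_rates = np.array([rate_of_change(r) for r in control_records])
    ctl_mean = float(control_rates.mean())
    ratios = np.array(
        [rate_of_change(r) - ctl_mean + 1.0 for r in heat_shock_records]
    )
    return RecoveryResult(
        animal_ids=[r.animal_id for r in heat_shock_records],
        ratios=ratios,
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        control_mean_rate=ctl_mean,
        n_heat_shock=len(heat_shock_records),
        n_control=len(control_records),
    )


@dataclass
class PunctaSummary:
    """Background-corrected puncta intensities and areas of one ROI."""

    roi_id: str
    punctum_intensities: np.ndarray  # corrected, clipped at 0
    punctum_areas: np.ndarray
    mean_intensity: float
    n_puncta: int


def summarize_puncta(
    roi_id: str,
    raw_intensities: Sequence[float],
    areas: Sequence[float],
    bg_points: Sequence[float],
    equal_roi_size: bool = True,
) -> PunctaSummary:
    """Corrected per-punctum intensities, their mean, and pass-through areas.

    Corrected intensities are clipped at 0 (with a warning) — a punctum
    dimmer than background carries no usable signal. An empty table yields
    mean 0 with n=0, matching a "not detected" phenotype. ``equal_roi_size``
    records the caller's assertion that ROI sizes matched across animals.
    """
    if not equal_roi_size:
        logger.warning("ROI sizes not asserted equal; intensities are not comparable")
    raw = np.asarray(raw_intensities, dtype=float)
    area = np.asarray(areas, dtype=float)
    if len(raw) != len(area):
        raise FormatError("intensity and area lists must have equal length")
    if np.any(area <= 0):
        raise FormatError("punctum areas must be positive")
    if len(raw) == 0:
        return PunctaSummary(roi_id, np.array([]), np.array([]), 0.0, 0)
    corrected = np.array([background_correct(v, bg_points) for v in raw])
    if np.any(corrected < 0):
        logger.warning(
            "ROI %s: %d punctum intensit(ies) below background, clipped to 0",
            roi_id, int((corrected < 0).sum()),
        )
        corrected = np.clip(corrected, 0.0, None)
    return PunctaSummary(
        roi_id=roi_id,
        punctum_intensities=corrected,
        punctum_areas=area,
        mean_intensity=float(corrected.mean()),
        n_puncta=len(corrected),
    )


# ---------------------------------------------------------------- file I/O

FLUOR_COLUMNS = (
    "animal_id", "condition",
    "roi_intact", "roi_bleach", "roi_after",
    "bg1_intact", "bg2_intact", "bg3_intact",
    "bg1_bleach", "bg2_bleach", "bg3_bleach",
    "bg1_after", "bg2_after", "bg3_after",
)


def read_fluorescence_records(path) -> list[FluorescenceRecord]:
    """Read records from delimited text with the columns in ``FLUOR_COLUMNS``."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in FLUOR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}'")
    out = []
    for _, row in df.iterrows():
        out.append(
            FluorescenceRecord(
                animal_id=str(row["animal_id"]),
                roi_intact=float(row["roi_intact"]),
                roi_bleached=float(row["roi_bleach"]),
                roi_after=float(row["roi_after"]),
                bg_intact=(row["bg1_intact"], row["bg2_intact"], row["bg3_intact"]),
                bg_bleached=(row["bg1_bleach"], row["bg2_bleach"], row["bg3_bleach"]),
                bg_after=(row["bg1_after"], row["bg2_after"], row["bg3_after"]),
                condition=str(row["condition"]),
            )
        )
    return out


def write_fluorescence_records(records: Sequence[FluorescenceRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "condition": r.condition,
                "roi_intact": r.roi_intact,
                "roi_bleach": r.roi_bleached,
                "roi_after": r.roi_after,
                **{f"bg{k+1}_intact": v for k, v in enumerate(r.bg_intact)},
                **{f"bg{k+1}_bleach": v for k, v in enumerate(r.bg_bleached)},
                **{f"bg{k+1}_after": v for k, v in enumerate(r.bg_after)},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
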