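"""SPECT semi-quantification: cylinder calibration and %ID/cc conversion.

A cylinder of known activity and volume is scanned once to calibrate the
scanner: the cylinder factor converts reconstructed ROI intensity into
activity concentration. ROI measurements then become %ID/cc via the
injected activity, and imaging series can be correlated against ex-vivo
biodistribution (%ID/g) with a Pearson coefficient and ordinary
least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedRatioError, ValidationError


@dataclass(frozen=True)
class CalibrationFactor:
    """Scanner calibration: activity per cc per ROI intensity unit.

    ``activity_unit`` documents the unit carried by ``source_activity`` (and
    therefore by the factor); conversions check it against the ROI
    measurement's unit.
    """

    factor: float
    source_activity: float
    cylinder_volume_cc: float
    activity_unit: str = "MBq"

    def __post_init__(self) -> None:
        if self.factor <= 0 or self.cylinder_volume_cc <= 0:
            raise ValidationError("factor and cylinder volume must be positive")


@dataclass(frozen=True)
class RoiMeasurement:
    """One ROI reading with the subject's injected activity."""

    region: str
    intensity: float
    time_h: float
    injected_activity: float
    activity_unit: str = "MBq"

    def __post_init__(self) -> None:
        if self.injected_activity <= 0:
            raise ValidationError("injected activity must be positive")
        if self.intensity < 0:
            raise ValidationError("ROI intensity must be >= 0")


def cylinder_factor(
    source_activity: float,
    roi_intensity_of_cylinder: float,
    cylinder_volume_cc: float,
    activity_unit: str = "MBq",
) -> CalibrationFactor:
    """Calibration factor = activity / (ROI intensity x volume)."""
    if source_activity <= 0 or roi_intensity_of_cylinder <= 0 or cylinder_volume_cc <= 0:
        raise ValidationError("all calibration inputs must be positive")
    return CalibrationFactor(
        factor=source_activity / (roi_intensity_of_cylinder * cylinder_volume_cc),
        source_activity=source_activity,
        cylinder_volume_cc=cylinder_volume_cc,
        activity_unit=activity_unit,
    )


def roi_to_pct_id_per_cc(m: RoiMeasurement, cf: CalibrationFactor) -> float:
    """%ID/cc = 100 x (intensity x factor) / injected activity."""
    if m.activity_unit != cf.activity_unit:
        raise ValidationError(
            f"unit mismatch: ROI in {m.activity_unit!r}, calibration in {cf.activity_unit!r}"
        )
    return 100.0 * (m.intensity * cf.factor) / m.injected_activity


def correlate(
    imaging_series: np.ndarray, biodist_series: np.ndarray
) -> tuple[float, float, float]:
    """Pearson r plus OLS slope/intercept of biodistribution on imaging.

    Series must be paired by (subject, time) upstream and have length >= 3.
    Returns ``(r, slope, intercept)``.
    """
    x = np.asarray(imaging_series, dtype=float)
    y = np.asarray(biodist_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedRatioError("correlation undefined: a series has zero variance")
    lr = stats.linregress(x, y)
    return float(lr.rvalue), float(lr.slope), float(lr.intercept)
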