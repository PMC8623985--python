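"""Dose reports, tumor-to-organ dose ratios and route comparison.

A :class:`DoseReport` mirrors the layout of a published dose table: one
absorbed dose per target organ in mSv/MBq, a sphere-model tumor dose in
mGy/MBq (numerically comparable because the radiation weighting factor is
1), plus total-body and effective dose summaries. Reports round-trip
through delimited text so externally computed tables (e.g. from licensed
phantom software) can be fed into the ratio and comparison operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import UndefinedRatioError, ValidationError


@dataclass
class DoseReport:
    """Per-target absorbed doses for one administration route."""

    route: str
    organ_doses_mSv_per_MBq: dict[str, float]
    tumor_sphere_dose_mGy_per_MBq: float | None = None
    sphere_mass_g: float | None = None
    total_body_dose_mSv_per_MBq: float | None = None
    effective_dose_mSv_per_MBq: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for organ, d in self.organ_doses_mSv_per_MBq.items():
            if not (d >= 0 and math.isfinite(d)):
                raise ValidationError(f"dose for {organ!r} must be finite and >= 0")
        t = self.tumor_sphere_dose_mGy_per_MBq
        if t is not None and not (t >= 0 and math.isfinite(t)):
            raise ValidationError("tumor sphere dose must be finite and >= 0")

    def to_csv(self, path: str | Path) -> None:
        rows = [{"target_organ": o, "absorbed_dose": d}
                for o, d in self.organ_doses_mSv_per_MBq.items()]
        if self.tumor_sphere_dose_mGy_per_MBq is not None:
            rows.append({"target_organ": "tumor_sphere",
                         "absorbed_dose": self.tumor_sphere_dose_mGy_per_MBq})
        if self.total_body_dose_mSv_per_MBq is not None:
            rows.append({"target_organ": "total body",
                         "absorbed_dose": self.total_body_dose_mSv_per_MBq})
        if self.effective_dose_mSv_per_MBq is not None:
            rows.append({"target_organ": "effective dose",
                         "absorbed_dose": self.effective_dose_mSv_per_MBq})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, route: str = "intratumoral") -> "DoseReport":
        df = pd.read_csv(path)
        required = {"target_organ", "absorbed_dose"}
        if not required.issubset(df.columns):
            raise ValidationError(f"dose report needs columns {sorted(required)}")
        doses: dict[str, float] = {}
        tumor = total = eff = None
        for rec in df.itertuples(index=False):
            organ = str(rec.target_organ).strip().lower()
            val = float(rec.absorbed_dose)
            if organ == "tumor_sphere":
                tumor = val
            elif organ == "total body":
                total = val
            elif organ == "effective dose":
                eff = val
            else:
                doses[organ] = val
        return cls(route=route, organ_doses_mSv_per_MBq=doses,
                   tumor_sphere_dose_mGy_per_MBq=tumor,
                   total_body_dose_mSv_per_MBq=total,
                   effective_dose_mSv_per_MBq=eff)


def format_ratio(value: float) -> str:
    """Display rounding convention: 1 decimal for |r| >= 1, 2 decimals below."""
    return f"{value:.1f}" if abs(value) >= 1.0 else f"{value:.2f}"


def dose_ratio(report: DoseReport, reference_organ: str) -> float:
    """Tumor-sphere dose over a reference organ dose (full precision).

    mGy numerator and mSv denominator are treated as numerically equal
    (radiation weighting factor 1 for beta/gamma emitters).
    """
    if report.tumor_sphere_dose_mGy_per_MBq is None:
        raise ValidationError("report has no tumor sphere dose")
    try:
        ref = report.organ_doses_mSv_per_MBq[reference_organ]
    except KeyError:
        raise ValidationError(f"no dose for reference organ {reference_organ!r}") from None
    if report.tumor_sphere_dose_mGy_per_MBq == 0.0:
        return 0.0
    if ref <= 0.0:
        raise UndefinedRatioError(f"reference organ {reference_organ!r} dose is 0")
    return report.tumor_sphere_dose_mGy_per_MBq / ref


@dataclass
class RouteComparison:
    """Paired intratumoral vs intravenous dose table with tumor ratios."""

    paired: pd.DataFrame  # organ, dose_intratumoral, dose_intravenous
    ratios: dict[str, dict[str, float]]  # route -> {reference organ -> ratio}
    sphere_mass_g: float | None
    only_in_intratumoral: tuple[str, ...]
    only_in_intravenous: tuple[str, ...]


def compare_routes(
    it_report: DoseReport,
    iv_report: DoseReport,
    reference_organs: tuple[str, ...] = ("brain", "thyroid"),
) -> RouteComparison:
    """Pair the two route reports organ-by-organ and compute tumor ratios.

    Organs present in only one report are listed in the discrepancy fields,
    never dropped silently.
    """
    it, iv = it_report.organ_doses_mSv_per_MBq, iv_report.organ_doses_mSv_per_MBq
    shared = sorted(set(it) & set(iv))
    paired = pd.DataFrame({
        "organ": shared,
        "dose_intratumoral": [it[o] for o in shared],
        "dose_intravenous": [iv[o] for o in shared],
    })
    ratios: dict[str, dict[str, float]] = {}
    for route, rep in (("intratumoral", it_report), ("intravenous", iv_report)):
        ratios[route] = {}
        for ref in reference_organs:
            if ref in rep.organ_doses_mSv_per_MBq and rep.tumor_sphere_dose_mGy_per_MBq is not None:
                ratios[route][ref] = dose_ratio(rep, ref)
    mass = it_report.sphere_mass_g or iv_report.sphere_mass_g
    return RouteComparison(
        paired=paired,
        ratios=ratios,
        sphere_mass_g=mass,
        only_in_intratumoral=tuple(sorted(set(it) - set(iv))),
        only_in_intravenous=tuple(sorted(set(iv) - set(it))),
    )
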