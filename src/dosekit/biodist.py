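"""Reading, validation and summarisation of biodistribution tables.

A biodistribution table holds per-animal, per-organ, per-timepoint
measurements of percent injected dose per gram of tissue (%ID/g), the raw
input of the dosimetry pipeline. Tables are delimited text with header
``animal_id,organ,time_h,pct_id_per_g`` (comma default, tab accepted).

The ``decay_corrected`` flag records whether the %ID/g values were corrected
back to injection time by the counting workflow (the usual convention); it
controls whether physical decay is added back during time-activity
integration downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedRatioError, ValidationError
from .organs import normalize_organ

REQUIRED_COLUMNS = ("animal_id", "organ", "time_h", "pct_id_per_g")

ROUTES = ("intratumoral", "intravenous")


@dataclass
class BiodistributionTable:
    """Validated multi-animal, multi-organ, multi-timepoint %ID/g table.

    Attributes
    ----------
    records:
        DataFrame with columns ``animal_id, organ, time_h, pct_id_per_g``;
        organ names are canonical (lower case).
    route:
        ``"intratumoral"`` or ``"intravenous"``.
    decay_corrected:
        True if %ID/g values are referenced to injection time.
    unknown_organs:
        Organ labels from the input that are not in the vocabulary. Their
        rows are kept (reported, never silently dropped) but are excluded
        from downstream extrapolation by virtue of having no mass entry.
    """

    records: pd.DataFrame
    route: str = "intratumoral"
    decay_corrected: bool = True
    unknown_organs: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        _validate_records(self.records)

    @property
    def organs(self) -> list[str]:
        return sorted(self.records["organ"].unique())

    @property
    def timepoints_h(self) -> np.ndarray:
        return np.sort(self.records["time_h"].unique())


def _validate_records(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValidationError("table has no records")
    neg = df.index[df["pct_id_per_g"] < 0]
    if len(neg):
        raise ValidationError(f"negative pct_id_per_g in row(s) {list(neg[:5])}")
    bad_t = df.index[df["time_h"] <= 0]
    if len(bad_t):
        raise ValidationError(f"non-positive time_h in row(s) {list(bad_t[:5])}")
    # Downstream fitting needs at least one organ observed at >=2 times.
    n_times = df.groupby("organ")["time_h"].nunique()
    if (n_times < 2).all():
        raise ValidationError(
            "no organ has measurements at two or more distinct timepoints; "
            "time-activity fitting is impossible"
        )


def load_biodistribution(
    path: str | Path | io.StringIO,
    route: str = "intratumoral",
    decay_corrected: bool = True,
    extra_organs: tuple[str, ...] = (),
) -> BiodistributionTable:
    """Load and validate a delimited-text biodistribution table.

    The delimiter is sniffed (comma default, tab accepted). Unknown organ
    names are reported via :class:`UserWarning` and listed on the returned
    table; rows are never silently dropped.
    """
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise FormatError(f"unreadable biodistribution file: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    for col in ("time_h", "pct_id_per_g"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r}") from exc

    unknown: list[str] = []
    canon = []
    for name in df["organ"].astype(str):
        c = normalize_organ(name, extra_organs)
        if c is None:
            if name not in unknown:
                unknown.append(name)
            c = name.strip().lower()
        canon.append(c)
    df = df.assign(organ=canon)
    if unknown:
        warnings.warn(
            f"unrecognised organ name(s) kept as-is: {', '.join(sorted(unknown))}",
            stacklevel=2,
        )
    return BiodistributionTable(
        records=df[list(REQUIRED_COLUMNS)],
        route=route,
        decay_corrected=decay_corrected,
        unknown_organs=tuple(sorted(unknown)),
    )


def write_biodistribution(table: BiodistributionTable, path: str | Path) -> None:
    """Write the records back to delimited text (full float precision)."""
    table.records.to_csv(path, index=False)


def summarize(table: BiodistributionTable) -> pd.DataFrame:
    """Per-(organ, time) mean, SD and animal count of %ID/g.

    SD is the sample standard deviation (ddof=1) for n >= 2 animals and 0
    for a single animal.
    """
    g = table.records.groupby(["organ", "time_h"])["pct_id_per_g"]
    out = g.agg(
        mean_pct_id_per_g="mean",
        sd_pct_id_per_g=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        n_animals="count",
    ).reset_index()
    return out.sort_values(["organ", "time_h"], ignore_index=True)


@dataclass(frozen=True)
class RatioResult:
    """A tumor-to-tissue style ratio with its dispersion."""

    value: float
    sd: float
    n: int
    method: str


def tissue_ratio(
    table: BiodistributionTable,
    numerator_organ: str,
    denominator_organ: str,
    time_h: float,
    method: str = "per_animal_mean",
) -> RatioResult:
    """Ratio of %ID/g between two organs at one timepoint.

    ``per_animal_mean`` pairs the two organs within each animal, then
    averages the per-animal ratios (the convention behind published
    tumor-to-muscle / tumor-to-blood rows); animals whose denominator is 0
    are excluded from the average. ``ratio_of_means`` divides the two
    summary means and propagates the SDs to first order.
    """
    df = table.records
    num = df[(df["organ"] == numerator_organ) & (df["time_h"] == time_h)]
    den = df[(df["organ"] == denominator_organ) & (df["time_h"] == time_h)]
    if num.empty or den.empty:
        raise ValidationError(
            f"both organs must be measured at t={time_h} h "
            f"({numerator_organ!r}: {len(num)} rows, {denominator_organ!r}: {len(den)} rows)"
        )

    if method == "ratio_of_means":
        mn, md = num["pct_id_per_g"].mean(), den["pct_id_per_g"].mean()
        if md == 0:
            raise UndefinedRatioError(
                f"mean {denominator_organ} %ID/g is 0 at t={time_h} h"
            )
        value = mn / md
        sn = float(np.std(num["pct_id_per_g"], ddof=1)) if len(num) > 1 else 0.0
        sd_ = float(np.std(den["pct_id_per_g"], ddof=1)) if len(den) > 1 else 0.0
        rel = np.hypot(sn / mn if mn else 0.0, sd_ / md)
        return RatioResult(value, abs(value) * rel, min(len(num), len(den)), method)

    if method == "per_animal_mean":
        pair = num.merge(den, on="animal_id", suffixes=("_num", "_den"))
        pair = pair[pair["pct_id_per_g_den"] > 0]
        if pair.empty:
            raise UndefinedRatioError(
                f"no animal has nonzero {denominator_organ} %ID/g at t={time_h} h"
            )
        ratios = pair["pct_id_per_g_num"] / pair["pct_id_per_g_den"]
        sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
        return RatioResult(float(ratios.mean()), sd, len(ratios), method)

    raise ValidationError(f"unknown ratio method {method!r}")
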