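"""Accessors for the packaged reference data.

The package ships, as plain delimited text under ``dosekit/data``:

* the published intratumoral biodistribution summary (mean +/- SD %ID/g for
  16 organs at 4/24/48/72 h) and its deterministic four-pseudo-animal
  expansion (exact cell means, best-effort SDs);
* the two published adult-human dose tables (intratumoral and intravenous
  routes) for ratio arithmetic and route comparison;
* reference adult organ masses and ICRP-60 tissue weights as YAML.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .biodist import BiodistributionTable, load_biodistribution
from .report import DoseReport


def _data_path(name: str):
    return resources.files("dosekit.data") / name


def intratumoral_summary() -> pd.DataFrame:
    """Published intratumoral summary: organ, time_h, mean and SD %ID/g."""
    with resources.as_file(_data_path("biodist_intratumoral_summary.csv")) as p:
        return pd.read_csv(p)


def intratumoral_table() -> BiodistributionTable:
    """Per-animal expansion of the intratumoral summary (4 pseudo-animals)."""
    with resources.as_file(_data_path("biodist_intratumoral_animals.csv")) as p:
        return load_biodistribution(p, route="intratumoral", decay_corrected=True)


def published_dose_report(route: str) -> DoseReport:
    """The published adult dose table for a route, as a DoseReport.

    Organ doses in mSv/MBq; the tumor sphere row (0.5 g) in mGy/MBq.
    """
    name = {
        "intratumoral": "dose_report_intratumoral.csv",
        "intravenous": "dose_report_intravenous.csv",
    }.get(route)
    if name is None:
        raise ValueError(f"unknown route {route!r}")
    with resources.as_file(_data_path(name)) as p:
        rep = DoseReport.from_csv(p, route=route)
    rep.sphere_mass_g = 0.5
    rep.provenance["source"] = "published adult dose table"
    return rep
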