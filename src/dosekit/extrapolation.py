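"""Mouse-to-human organ uptake extrapolation.

A mouse organ concentration C (%ID/g) is converted to the percent of
injected activity contained in the corresponding whole human organ by the
relative-organ-mass scaling

    %IA/organ (human) = C x TBW_mouse[kg] x m_organ[g] / TBW_human[kg]

i.e. the mouse concentration is first expressed per unit of mouse body
weight, then multiplied by the human organ mass normalised to human body
weight. The scaling is linear in both the concentration and the organ mass.

Organ masses come from a reference adult phantom table bundled with the
package (overridable per run); organs with no phantom counterpart (urine)
are excluded explicitly and listed in the returned provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class SpeciesParams:
    """Total body weights of the source and target species (kg)."""

    mouse_total_body_weight_kg: float = 0.025
    human_total_body_weight_kg: float = 73.0

    def __post_init__(self) -> None:
        if self.mouse_total_body_weight_kg <= 0 or self.human_total_body_weight_kg <= 0:
            raise ValidationError("body weights must be positive")


@dataclass
class OrganMassTable:
    """Map organ -> reference adult organ mass in grams, with provenance."""

    masses_g: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {o: m for o, m in self.masses_g.items() if m <= 0}
        if bad:
            raise ValidationError(f"non-positive organ mass(es): {bad}")

    def __getitem__(self, organ: str) -> float:
        try:
            return self.masses_g[organ]
        except KeyError:
            raise ValidationError(f"no reference mass for organ {organ!r}") from None

    def __contains__(self, organ: str) -> bool:
        return organ in self.masses_g

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OrganMassTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(masses_g={k: float(v) for k, v in doc["masses_g"].items()},
                   provenance=doc.get("provenance", ""))

    @classmethod
    def default_adult_male(cls) -> "OrganMassTable":
        ref = resources.files("dosekit.data") / "organ_masses_adult_male.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def extrapolate(conc_pct_id_per_g: float, sp: SpeciesParams, organ_mass_g: float) -> float:
    """Human whole-organ uptake (%IA) from a mouse concentration (%ID/g)."""
    if conc_pct_id_per_g < 0:
        raise ValidationError("concentration must be >= 0")
    if organ_mass_g <= 0:
        raise ValidationError("organ mass must be positive")
    return (
        conc_pct_id_per_g
        * sp.mouse_total_body_weight_kg
        * organ_mass_g
        / sp.human_total_body_weight_kg
    )


@dataclass
class HumanUptake:
    """Extrapolated human uptake points plus exclusion provenance."""

    points: pd.DataFrame  # columns: organ, time_h, pct_ia_per_organ
    excluded: tuple[str, ...] = field(default_factory=tuple)
    mass_overrides: dict[str, float] = field(default_factory=dict)


def extrapolate_table(
    summaries: pd.DataFrame,
    sp: SpeciesParams,
    masses: OrganMassTable,
    exclude: tuple[str, ...] = ("urine",),
    mass_overrides: dict[str, float] | None = None,
) -> HumanUptake:
    """Extrapolate a per-(organ, time) mean-uptake summary to human organs.

    Parameters
    ----------
    summaries:
        Output of :func:`dosekit.biodist.summarize` (or any frame with
        ``organ, time_h, mean_pct_id_per_g`` columns).
    exclude:
        Organs dropped from extrapolation (listed in the result provenance);
        by default only urine, which is voided and has no phantom organ.
    mass_overrides:
        Per-run organ mass replacements, e.g. ``{"tumor": 0.5}`` to treat
        the tumor as a 0.5 g sphere.
    """
    mass_overrides = dict(mass_overrides or {})
    rows = []
    skipped = []
    for rec in summaries.itertuples(index=False):
        organ = rec.organ
        if organ in exclude:
            skipped.append(organ)
            continue
        if organ in mass_overrides:
            m = mass_overrides[organ]
            if m <= 0:
                raise ValidationError(f"override mass for {organ!r} must be positive")
        elif organ in masses:
            m = masses[organ]
        else:
            raise ValidationError(f"no reference mass for organ {organ!r}")
        rows.append({
            "organ": organ,
            "time_h": rec.time_h,
            "pct_ia_per_organ": extrapolate(rec.mean_pct_id_per_g, sp, m),
        })
    points = pd.DataFrame(rows, columns=["organ", "time_h", "pct_ia_per_organ"])
    return HumanUptake(points=points,
                       excluded=tuple(sorted(set(skipped))),
                       mass_overrides=mass_overrides)
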