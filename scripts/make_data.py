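"""Regenerate the packaged data files under src/dosekit/data/.

The per-animal intratumoral fixture is a deterministic expansion of the
printed summary table: four pseudo-animals per (organ, time) cell at
symmetric offsets around the printed mean, scaled to the printed SD where
possible (offsets shrink so no value goes negative; the mean is always
exact). Run from the repository root: python scripts/make_data.py
"""

from pathlib import Path

import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "dosekit" / "data"

# Printed intratumoral biodistribution summary: organ -> [(mean, sd)] at 4/24/48/72 h.
TIMES = [4.0, 24.0, 48.0, 72.0]
INTRATUMORAL = {
    "blood": [(5.43, 3.78), (0.16, 0.03), (0.21, 0.07), (0.15, 0.02)],
    "heart": [(1.14, 0.65), (0.27, 0.13), (0.23, 0.05), (0.17, 0.09)],
    "lung": [(2.59, 0.95), (0.81, 0.44), (0.62, 0.33), (0.54, 0.27)],
    "liver": [(8.91, 4.50), (17.68, 6.47), (10.43, 4.01), (7.85, 5.02)],
    "stomach": [(0.59, 0.10), (0.36, 0.07), (0.39, 0.10), (0.31, 0.02)],
    "small intestine": [(0.81, 0.25), (0.61, 0.29), (0.74, 0.38), (0.24, 0.03)],
    "large intestine": [(0.51, 0.17), (0.20, 0.06), (0.25, 0.09), (0.15, 0.07)],
    "spleen": [(5.99, 1.34), (8.49, 2.74), (4.85, 2.77), (2.53, 2.11)],
    "pancreas": [(0.65, 0.25), (0.12, 0.05), (0.13, 0.04), (0.14, 0.03)],
    "kidney": [(8.97, 1.79), (7.04, 2.07), (4.31, 0.79), (4.23, 1.56)],
    "bone": [(0.65, 0.09), (0.88, 0.06), (1.74, 0.41), (2.20, 0.89)],
    "muscle": [(0.28, 0.14), (0.07, 0.10), (0.10, 0.05), (0.04, 0.05)],
    "tumor": [(125.09, 27.26), (120.08, 51.32), (35.62, 6.85), (61.44, 14.81)],
    "bone marrow": [(2.12, 1.35), (0.55, 1.01), (2.15, 0.86), (0.00, 0.00)],
    "brain": [(0.16, 0.08), (0.02, 0.03), (0.02, 0.01), (0.03, 0.04)],
    "urine": [(183.23, 81.08), (11.41, 10.71), (2.04, 1.10), (2.49, 2.87)],
}

# Printed adult-human dose tables (mSv/MBq; tumor sphere row in mGy/MBq).
DOSES_IT = {
    "adrenals": 4.92e-3, "brain": 2.34e-3, "breasts": 1.50e-3,
    "gallbladder wall": 7.43e-3, "lli wall": 5.06e-3, "small intestine": 5.62e-3,
    "stomach wall": 7.17e-3, "uli wall": 2.52e-3, "heart wall": 2.22e-2,
    "kidneys": 1.35e-1, "liver": 3.29e-1, "lungs": 2.61e-2, "muscle": 3.53e-3,
    "ovaries": 1.48e-3, "pancreas": 1.18e-2, "red marrow": 2.13e-3,
    "skin": 1.25e-3, "spleen": 1.38e-1, "testes": 9.93e-4, "thymus": 1.64e-3,
    "thyroid": 1.22e-3, "urinary bladder wall": 1.14e-3, "uterus": 1.38e-3,
}
EXTRA_IT = {"tumor_sphere": 3.55, "total body": 1.69e-2, "effective dose": 2.51e-2}
DOSES_IV = {
    "adrenals": 9.06e-2, "brain": 3.86e-3, "breasts": 7.09e-2,
    "gallbladder wall": 1.08e-1, "lli wall": 7.77e-2, "small intestine": 8.76e-2,
    "stomach wall": 8.14e-2, "uli wall": 8.02e-2, "heart wall": 2.14e-2,
    "kidneys": 1.60e-1, "liver": 1.97, "lungs": 6.37e-2, "muscle": 1.14e-2,
    "ovaries": 7.40e-2, "pancreas": 5.01e-2, "red marrow": 5.71e-2,
    "skin": 6.83e-2, "spleen": 1.37, "testes": 6.95e-2, "thymus": 7.19e-2,
    "thyroid": 7.03e-2, "urinary bladder wall": 7.23e-2, "uterus": 7.43e-2,
}
EXTRA_IV = {"tumor_sphere": 3.82e-2, "total body": 1.31e-1, "effective dose": 1.71e-1}


def pseudo_animals(mean: float, sd: float, n: int = 4) -> list[float]:
    """Symmetric values with exact mean and best-effort sample SD, all >= 0."""
    assert n == 4, "layout fixed at four pseudo-animals"
    k = sd / (20.0 / 3.0) ** 0.5  # sample SD of offsets [-3,-1,1,3]*k is k*sqrt(20/3)
    if mean - 3.0 * k < 0.0:
        k = mean / 3.0  # shrink so the lowest animal sits at zero
    return [mean + o * k for o in (-3.0, -1.0, 1.0, 3.0)]


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    rows = []
    for organ, cells in INTRATUMORAL.items():
        for t, (m, s) in zip(TIMES, cells):
            rows.append({"organ": organ, "time_h": t,
                         "mean_pct_id_per_g": m, "sd_pct_id_per_g": s})
    pd.DataFrame(rows).to_csv(DATA / "biodist_intratumoral_summary.csv", index=False)

    arows = []
    for organ, cells in INTRATUMORAL.items():
        for t, (m, s) in zip(TIMES, cells):
            for i, v in enumerate(pseudo_animals(m, s), start=1):
                arows.append({"animal_id": f"m{i}", "organ": organ,
                              "time_h": t, "pct_id_per_g": repr(max(v, 0.0))})
    pd.DataFrame(arows).to_csv(DATA / "biodist_intratumoral_animals.csv", index=False)

    for name, doses, extra in (
        ("dose_report_intratumoral.csv", DOSES_IT, EXTRA_IT),
        ("dose_report_intravenous.csv", DOSES_IV, EXTRA_IV),
    ):
        drows = [{"target_organ": o, "absorbed_dose": d} for o, d in doses.items()]
        drows += [{"target_organ": o, "absorbed_dose": d} for o, d in extra.items()]
        pd.DataFrame(drows).to_csv(DATA / name, index=False)

    print("wrote data files to", DATA)


if __name__ == "__main__":
    main()
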