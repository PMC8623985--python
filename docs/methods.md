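# Methods

## Scope and data model

`dosekit` estimates human organ absorbed doses from mouse biodistribution
data for a beta/gamma-emitting radiopharmaceutical. The raw input is a
multi-animal table of %ID/g values per organ and time post-injection
(delimited text, `animal_id,organ,time_h,pct_id_per_g`). The packaged
reference dataset is an intratumoral ¹⁷⁷Lu-nanoparticle study: 16 organs
(tumor, urine and blood included as pseudo-organs) at 4, 24, 48 and 72 h,
four animals per cell. Only mean ± SD summary cells are published for that
study, so the packaged per-animal file is a deterministic expansion: four
pseudo-animals at symmetric offsets around each printed mean, scaled to the
printed sample SD where all values stay non-negative (the offsets shrink
otherwise, preserving the mean exactly and the SD best-effort). Downstream
doses depend only on the means, which the expansion reproduces exactly.

The `decay_corrected` flag on a table records whether %ID/g values are
referenced to injection time (the usual gamma-counting convention, and the
default). It decides whether the fitted slope is biological clearance or
the effective (biological + physical) rate.

## Species extrapolation

Mouse concentration C (%ID/g) maps to human whole-organ uptake by relative
organ mass:

    %IA/organ = C × TBW_mouse[kg] × m_organ[g] / TBW_human[kg]

Defaults: 0.025 kg mouse, 73 kg adult. Organ masses are the
Cristy–Eckerman-style reference adult values bundled as YAML (liver 1910 g,
kidneys 299 g, spleen 183 g, ...; composites documented in the file
header); the study the defaults reproduce named only the phantom software
it used, not the masses, so the bundled table is our own provenance-noted
choice. Three interpretive decisions, made once:

* **Tumor** is extrapolated with its sphere mass (default 0.5 g) as the
  "organ mass". This is the only reading under which the published tumor
  sphere dose is on the right order of magnitude; keeping the tumor
  activity on the mouse side (%ID/g × 0.5 g without the body-weight ratio)
  inflates it ~2900-fold.
* **Blood** gets a 5300 g reference blood-pool mass and its disintegrations
  are routed to a "total body" remainder source (uniformly distributed
  activity). Under the local-deposition S model that source doses only the
  total-body target.
* **Urine** is voided activity: excluded from extrapolation, listed in the
  result provenance.

## Time–activity fitting and integration

Per organ, the mean uptake series is fitted log-linearly from the observed
peak onward (`monoexp_from_peak`); the peak is the argmax, ties toward the
earlier time, so a liver-like series peaking at 24 h drops the 4 h point
from the regression but keeps it for optional pre-peak trapezoids. If the
peak is the last timepoint (bone-like monotone uptake) the whole series is
fitted and the non-negative slope clamps λ_bio to 0 — the slowest allowed
clearance is physical decay alone, which keeps the integral finite and is
conservative (dose-maximising). When clamping, the level A₀ is refit as the
geometric mean of the window (least squares at fixed slope). Zeros in the
window are dropped; fewer than two positive points is an error, except the
all-zero series, which is a valid zero-activity organ.

Integration is analytic. With decay-corrected input,

    Ã = 3600 × (A₀/100) / (λ_bio + λ_phys)   [MBq·s per MBq]

for `ignore_pre_peak` (the default: the back-extrapolated exponential is
integrated from t = 0). `trapezoid_pre_peak` instead ramps linearly from
zero activity at t = 0 through the decay-weighted observed pre-peak points
and attaches the exponential tail at the peak; it is always ≤ the default
for the same fit. Both forms agree with adaptive quadrature of the same
piecewise model to well within 0.1% (property-tested), and Ã can never
exceed the pure-physical-decay bound 3600/λ_phys ≈ 8.29 × 10⁵ MBq·s/MBq
for A₀ ≤ 100 %IA.

The defaults (decay-corrected input, post-peak fit, `ignore_pre_peak`)
were fixed as the package's standard method; on the reference dataset they
put the recomputed liver dose within ~6% of the published phantom-software
value.

## Decay data

¹⁷⁷Lu defaults: T½ = 159.6 h; principal β branch 0.497 MeV endpoint at 78%
yield; 0.208 MeV γ at 11%; mean β range 670 μm. The non-penetrating energy
per decay Δ_np = 0.147 MeV is a stored constant with provenance: the
yield-weighted mean of allowed-shape β spectra for the three main branches
(computed by `mean_beta_energy`, Coulomb-corrected) gives ≈ 0.134 MeV,
and conversion/Auger electrons account for the remainder; 0.147 MeV matches
published decay-data tabulations. The penetrating energy Δ_p defaults to
the yield-weighted γ sum (0.0229 MeV/decay from the single configured
branch; configurable if more branches are added).

## Dose models

**Organ doses** follow the MIRD schema D(t) = Σ_s Ã(s) × S(t←s). Licensed
phantom S-value tables cannot be redistributed, so the matrix is generated:

* `local_np_only` — S(o←o) = Δ_np/m_o (J per decay per kg, scaled to
  mGy per MBq·s), all cross terms zero. Exact for pure local deposition;
  for ¹⁷⁷Lu the β self-dose dominates, so this captures the leading term.
* `local_np_plus_uniform_photon` (pipeline default) — adds a uniform
  whole-body photon bath S_γ = Δ_p × AF_body / TBW for every pair, with
  AF_body = 0.3 a configurable order-of-magnitude whole-body photon
  absorbed fraction.

The approximation error against full phantom Monte Carlo S-values is
organ-dependent but bounded in practice by a few tens of percent for
β-dominated self-irradiation; recomputed doses for the reference dataset
land within ~6% (liver), ~20% (kidney), ~12% (spleen) of the published
phantom-software table. Users with licensed S-values can import them via
the delimited-text S-matrix interface.

**Tumor dose** uses the unit-density sphere self-dose model:
D = Ã × (Δ_np φ_np + Δ_p φ_p)/m, with the edge-loss non-penetrating
absorbed fraction φ_np = 1 − (3/4)(r_β/R) (valid for r_β ≪ R, clamped to
(0, 1]; φ_np ≈ 0.90 for 0.5 g) and a small constant photon absorbed
fraction φ_p = 0.03 typical of gram-scale spheres. This closed form is the
bluntest approximation in the package: it reproduces the published 0.5 g
sphere dose only to within ~50%, which is the stated expectation for the
sphere target.

**Effective dose** applies ICRP-60 tissue weighting factors (the set used
by the era's phantom software). Weighted tissues with no computed dose
(esophagus, bladder, breast are not in a mouse panel) contribute zero with
a logged warning; the remainder weight takes the mean of unweighted
computed organ doses. Organ doses are reported in mSv/MBq and sphere doses
in mGy/MBq; the two are numerically equal for β/γ radiation (w_R = 1), and
tumor-to-organ ratios divide them directly. Ratios are computed at full
precision and displayed with one decimal above 1 and two below.

## Synthetic data

`KineticScenario` draws per-animal, per-organ values from ground-truth
curves: pure clearance A₀e^(−λt), uptake-then-clearance
A₀(1−e^(−k·t))e^(−λt) (exercises the clamping path), or a tabulated mean
curve. Noise is multiplicative log-normal with unit mean (σ² = ln(1+CV²)),
matching the positive, right-skewed character of biodistribution data;
generation is deterministic under the scenario seed. The bundled
`intratumoral_like` scenario carries the published intratumoral mean curves
as tabulated truth (they are non-monotone — the tumor dips at 48 h and
rises at 72 h — so no single parametric form can match them) with CV = 0 by
default; `intravenous_like` is a parametric liver/spleen-dominant scenario
typical of nanoparticle clearance through the reticuloendothelial system.

What the generator does **not** emulate: inter-animal kinetic heterogeneity
(noise is i.i.d. per measurement, not per animal), multi-compartment
washout, partial-volume or counting dead-time effects. Passing recovery
tests therefore demonstrates correctness of the fitting/integration chain
under the stated noise model, not robustness to real-world kinetic model
misfit.

## Verification sizes and numerics

The test suite uses 200–500 seeded replicates for stochastic-recovery
checks (median |bias| of λ_bio < 15% and of Ã < 20% at CV = 10%, n = 4
animals), 1000 random fits against the quadrature oracle (0.1% agreement),
and exact (≥6 significant digits) recovery on noiseless series. Ties in
peak detection go to the earlier timepoint; ratios are undefined (an error,
not NaN) when a denominator is zero; sample SD (ddof = 1) is used for n ≥ 2
animals and 0 for a single animal.

## Known limitations

* Generated S-values ignore organ-to-organ β/γ cross-fire geometry; organs
  dominated by cross-irradiation (e.g. ovaries, testes in an intratumoral
  study) are underestimated by `local_np_only`.
* The sphere photon absorbed fraction is a constant, not a function of
  sphere mass.
* Mono-exponential kinetics only; a series that is genuinely
  multi-exponential (blood) is summarised by its dominant post-peak decay.
* The published per-animal tumor-to-muscle/blood ratios use unpublished
  per-animal pairings and cannot be reproduced from summary means; both
  ratio conventions are provided but only the ratio-of-means values are
  asserted against arithmetic.
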