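"""Time-activity curve fitting and time-integrated activity.

Each source organ's human uptake series A(t) (%IA at the sampled hours
post-injection) is fitted with a single exponential from the observed peak
onward (log-linear least squares). If the input values are decay-corrected,
the fitted slope is the biological clearance constant lambda_bio; physical
decay is restored analytically during integration. The time-integrated
activity per unit injected activity,

    a_tilde = integral_0^inf A(t)/100 * exp(-lambda_phys * t) dt   [decay-corrected input]

equals the number of disintegrations in the organ per becquerel-second
injected; it is exposed in MBq*s per MBq injected (3600 s/h converts the
hour-based closed form). Rising curves (bone-like late uptake) are handled
by clamping lambda_bio at zero — the slowest clearance allowed is physical
decay alone, which keeps the integral finite and is conservative for dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError

#: MeV -> joule
MEV_TO_J = 1.602176634e-13

#: Mean energy per decay carried by non-penetrating emissions of Lu-177
#: (beta spectrum mean ~0.134 MeV plus conversion/Auger electrons), as
#: tabulated in published decay data. The allowed-shape beta spectrum mean
#: computed by mean_beta_energy() reproduces the beta part; the constant is
#: stored rather than computed because the conversion-electron lines are not
#: derivable from the beta endpoints alone.
LU177_DELTA_NP_MEV = 0.147


@dataclass(frozen=True)
class DecayData:
    """Radionuclide physics needed for dosimetry (defaults: Lu-177).

    Energies in MeV, times in hours. ``delta_np_MeV_per_decay`` is the mean
    energy per decay of non-penetrating emissions (betas + conversion/Auger
    electrons, absorbed locally); ``delta_p_MeV_per_decay`` the penetrating
    (photon) mean energy per decay, by default the yield-weighted sum of the
    configured gamma branches.
    """

    half_life_h: float = 6.65 * 24.0
    beta_branches: tuple[tuple[float, float], ...] = ((0.497, 0.78),)
    gamma_branches: tuple[tuple[float, float], ...] = ((0.208, 0.11),)
    delta_np_MeV_per_decay: float = LU177_DELTA_NP_MEV
    delta_p_MeV_per_decay: float | None = None
    mean_beta_range_um: float = 670.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValidationError("half-life must be positive")
        for e, y in (*self.beta_branches, *self.gamma_branches):
            if e < 0 or not (0.0 <= y <= 1.0):
                raise ValidationError("branch energies must be >= 0 and yields in [0, 1]")
        if self.delta_np_MeV_per_decay < 0:
            raise ValidationError("delta_np must be >= 0")
        if self.delta_p_MeV_per_decay is not None and self.delta_p_MeV_per_decay < 0:
            raise ValidationError("delta_p must be >= 0")

    @property
    def lambda_phys_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    @property
    def delta_p(self) -> float:
        """Penetrating mean energy per decay (MeV)."""
        if self.delta_p_MeV_per_decay is not None:
            return self.delta_p_MeV_per_decay
        return sum(e * y for e, y in self.gamma_branches)

    @property
    def delta_np(self) -> float:
        """Non-penetrating mean energy per decay (MeV)."""
        return self.delta_np_MeV_per_decay


def mean_beta_energy(emax_mev: float, z_daughter: int = 72, coulomb: bool = True,
                     n_grid: int = 4000) -> float:
    """Mean kinetic energy of an allowed-shape beta-minus spectrum.

    N(W) dW ~ F(Z, W) p W (W0 - W)^2 dW with W the total electron energy in
    electron-mass units and F the non-relativistic Fermi Coulomb correction
    2*pi*eta / (1 - exp(-2*pi*eta)), eta = alpha * Z * W / p. Used to cross-
    check the non-penetrating energy default against published decay data.
    """
    if emax_mev <= 0:
        raise ValidationError("endpoint energy must be positive")
    mec2 = 0.51099895  # MeV
    w0 = 1.0 + emax_mev / mec2
    # kinetic energy grid, excluding the endpoints where N -> 0
    t = np.linspace(1e-6, emax_mev - 1e-9, n_grid)
    w = 1.0 + t / mec2
    p = np.sqrt(np.maximum(w * w - 1.0, 0.0))
    shape = p * w * (w0 - w) ** 2
    if coulomb:
        alpha = 1.0 / 137.035999
        eta = alpha * z_daughter * w / p
        x = 2.0 * np.pi * eta
        shape = shape * x / (1.0 - np.exp(-x))
    return float(np.trapezoid(shape * t, t) / np.trapezoid(shape, t))


@dataclass
class TacFit:
    """Result of a mono-exponential time-activity fit for one organ."""

    organ: str
    A0_pct_ia: float
    lambda_bio_per_h: float
    lambda_phys_per_h: float
    method: str = "monoexp_from_peak"
    decay_corrected: bool = True
    peak_time_h: float = 0.0
    fit_window: tuple[float, ...] = field(default_factory=tuple)
    pre_peak_points: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    rms_log_residual: float = 0.0
    is_zero: bool = False

    def __post_init__(self) -> None:
        if self.A0_pct_ia < 0:
            raise ValidationError("A0 must be >= 0")
        if self.lambda_bio_per_h < 0:
            raise ValidationError("lambda_bio must be >= 0 (clamped upstream)")

    @property
    def lambda_eff_per_h(self) -> float:
        return self.lambda_bio_per_h + self.lambda_phys_per_h

    def activity_fraction(self, t_h: float) -> float:
        """Instantaneous activity as a fraction of injected, decay included."""
        if self.is_zero:
            return 0.0
        return (self.A0_pct_ia / 100.0) * math.exp(-self.lambda_eff_per_h * t_h)


def fit_monoexponential(
    times_h: np.ndarray,
    values_pct_ia: np.ndarray,
    decay: DecayData,
    decay_corrected: bool = True,
    organ: str = "",
) -> TacFit:
    """Log-linear mono-exponential fit from the observed peak onward.

    The peak is the argmax of the series (ties broken toward the earlier
    timepoint); points before it are kept aside for optional trapezoidal
    integration. Zeros inside the fit window are dropped from the
    regression; fewer than two positive points is a fit error, except the
    all-zero series which yields a valid zero-activity fit.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values_pct_ia, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1-D arrays of equal length")
    if np.any(v < 0):
        raise ValidationError("uptake values must be >= 0")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if len(np.unique(t)) < 2:
        raise FitError(f"{organ or 'series'}: need >= 2 distinct timepoints")

    lam_phys = decay.lambda_phys_per_h
    if np.all(v == 0.0):
        return TacFit(organ=organ, A0_pct_ia=0.0, lambda_bio_per_h=0.0,
                      lambda_phys_per_h=lam_phys, decay_corrected=decay_corrected,
                      fit_window=tuple(t), is_zero=True)

    i_peak = int(np.argmax(v))  # first maximum -> earlier timepoint on ties
    t_peak = t[i_peak]
    in_window = t >= t_peak
    if (v[in_window] > 0).sum() < 2:
        # Peak at (or near) the last timepoint: a rising curve. Fit the whole
        # series instead; the non-negative slope is clamped below.
        t_peak = t[0]
        in_window = t >= t_peak
    tw, vw = t[in_window], v[in_window]
    pos = vw > 0
    if pos.sum() < 2:
        raise FitError(
            f"{organ or 'series'}: fewer than 2 positive points in the fit window"
        )
    tw, vw = tw[pos], vw[pos]

    y = np.log(vw)
    slope, intercept = np.polyfit(tw, y, 1)
    lam_min = 0.0 if decay_corrected else lam_phys
    lam_fit = -slope  # lambda_bio if decay corrected, lambda_eff otherwise
    if lam_fit < lam_min:
        # Rising (or slower-than-physical) curve: clamp and refit the level.
        lam_fit = lam_min
        intercept = float(np.mean(y + lam_fit * tw))
    a0 = math.exp(intercept)
    lam_bio = lam_fit if decay_corrected else lam_fit - lam_phys
    lam_bio = max(lam_bio, 0.0)
    if not decay_corrected:
        # intercept already at t=0 where the decay factor is 1
        pass
    resid = y - (intercept - lam_fit * tw)
    pre = tuple(
        (float(ti), float(vi)) for ti, vi in zip(t[~in_window], v[~in_window])
    )
    return TacFit(
        organ=organ,
        A0_pct_ia=a0,
        lambda_bio_per_h=lam_bio,
        lambda_phys_per_h=lam_phys,
        decay_corrected=decay_corrected,
        peak_time_h=float(t_peak),
        fit_window=tuple(float(x) for x in tw),
        pre_peak_points=pre,
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass(frozen=True)
class TimeIntegratedActivity:
    """Disintegrations per unit injected activity for one source organ.

    ``a_tilde_MBq_s_per_MBq`` is the time integral of the organ activity per
    MBq injected, i.e. 1e6 x (number of disintegrations per MBq injected).
    """

    organ: str
    a_tilde_MBq_s_per_MBq: float
    fit: TacFit
    peak_handling: str = "ignore_pre_peak"

    def __post_init__(self) -> None:
        a = self.a_tilde_MBq_s_per_MBq
        if not (a >= 0 and math.isfinite(a)):
            raise ValidationError("a_tilde must be finite and >= 0")


def integrate(
    fit: TacFit,
    decay: DecayData,
    peak_handling: str = "ignore_pre_peak",
) -> TimeIntegratedActivity:
    """Analytic time-integrated activity of a fitted curve.

    ``ignore_pre_peak`` integrates the back-extrapolated exponential over
    [0, inf): a_tilde = 3600 * (A0/100) / lambda_eff. ``trapezoid_pre_peak``
    instead rises linearly from zero activity at t=0 through the observed
    pre-peak points (decay-weighted) and attaches the analytic exponential
    tail from the peak time.
    """
    if fit.is_zero:
        return TimeIntegratedActivity(fit.organ, 0.0, fit, peak_handling)
    lam_eff = fit.lambda_eff_per_h
    lam_phys = fit.lambda_phys_per_h
    frac0 = fit.A0_pct_ia / 100.0

    if peak_handling == "ignore_pre_peak":
        a_tilde_h = frac0 / lam_eff
    elif peak_handling == "trapezoid_pre_peak":
        # effective (decay-inclusive) activity at the pre-peak knots
        knots_t = [0.0]
        knots_a = [0.0]
        for ti, vi in fit.pre_peak_points:
            eff = (vi / 100.0) * (math.exp(-lam_phys * ti) if fit.decay_corrected else 1.0)
            knots_t.append(ti)
            knots_a.append(eff)
        tp = fit.peak_time_h
        knots_t.append(tp)
        knots_a.append(frac0 * math.exp(-lam_eff * tp))
        a_tilde_h = float(np.trapezoid(knots_a, knots_t))
        a_tilde_h += frac0 * math.exp(-lam_eff * tp) / lam_eff
    else:
        raise ValidationError(f"unknown peak_handling {peak_handling!r}")

    return TimeIntegratedActivity(fit.organ, 3600.0 * a_tilde_h, fit, peak_handling)


def build_all_tia(
    uptake_points: pd.DataFrame,
    decay: DecayData,
    decay_corrected: bool = True,
    peak_handling: str = "ignore_pre_peak",
) -> tuple[list[TimeIntegratedActivity], pd.DataFrame]:
    """Fit and integrate every organ in a human-uptake point table.

    Returns the TIAs plus a per-organ diagnostics frame (fit parameters,
    window, residuals) suitable for a delimited-text report.
    """
    tias: list[TimeIntegratedActivity] = []
    diag_rows = []
    for organ, grp in uptake_points.groupby("organ", sort=True):
        fit = fit_monoexponential(
            grp["time_h"].to_numpy(), grp["pct_ia_per_organ"].to_numpy(),
            decay, decay_corrected=decay_corrected, organ=str(organ),
        )
        tia = integrate(fit, decay, peak_handling=peak_handling)
        tias.append(tia)
        diag_rows.append({
            "organ": organ,
            "A0_pct_ia": fit.A0_pct_ia,
            "lambda_bio_per_h": fit.lambda_bio_per_h,
            "lambda_eff_per_h": fit.lambda_eff_per_h,
            "peak_time_h": fit.peak_time_h,
            "n_fit_points": len(fit.fit_window),
            "rms_log_residual": fit.rms_log_residual,
            "a_tilde_MBq_s_per_MBq": tia.a_tilde_MBq_s_per_MBq,
            "method": fit.method,
            "peak_handling": peak_handling,
        })
    return tias, pd.DataFrame(diag_rows)
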