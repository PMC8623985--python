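"""Time-activity fitting, integration and the decay-data defaults."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from dosekit import (DecayData, TacFit, build_all_tia, fit_monoexponential,
                     integrate, mean_beta_energy)
from dosekit.errors import FitError, ValidationError

TIMES = np.array([4.0, 24.0, 48.0, 72.0])


def quadrature_a_tilde(fit: TacFit, peak_handling: str) -> float:
    """Independent numerical oracle for the time-integrated activity.

    Integrates the same piecewise model with adaptive quadrature: linear
    ramp through the (decay-weighted) pre-peak knots when requested, then
    the fitted exponential tail. Returns MBq*s per MBq.
    """
    lam_eff = fit.lambda_eff_per_h
    lam_phys = fit.lambda_phys_per_h

    def tail(t):
        return (fit.A0_pct_ia / 100.0) * math.exp(-lam_eff * t)

    if fit.is_zero:
        return 0.0
    if peak_handling == "ignore_pre_peak":
        val, _ = quad(tail, 0.0, np.inf)
        return 3600.0 * val
    knots_t = [0.0] + [t for t, _ in fit.pre_peak_points] + [fit.peak_time_h]
    knots_a = [0.0]
    for t, v in fit.pre_peak_points:
        w = math.exp(-lam_phys * t) if fit.decay_corrected else 1.0
        knots_a.append(v / 100.0 * w)
    knots_a.append(tail(fit.peak_time_h))
    ramp = 0.0
    for i in range(len(knots_t) - 1):
        seg, _ = quad(lambda t: np.interp(t, knots_t, knots_a),
                      knots_t[i], knots_t[i + 1])
        ramp += seg
    tail_int, _ = quad(tail, fit.peak_time_h, np.inf)
    return 3600.0 * (ramp + tail_int)


class TestFit:
    def test_noiseless_exact_recovery(self, decay):
        v = 10.0 * np.exp(-0.01 * TIMES)
        fit = fit_monoexponential(TIMES, v, decay, decay_corrected=True)
        assert fit.A0_pct_ia == pytest.approx(10.0, rel=1e-9)
        assert fit.lambda_bio_per_h == pytest.approx(0.01, rel=1e-9)
        assert fit.peak_time_h == 4.0

    def test_rising_series_clamps_to_physical_decay(self, decay):
        # skeletal late-uptake pattern: monotone rise over the study window
        fit = fit_monoexponential(TIMES, np.array([0.65, 0.88, 1.74, 2.20]),
                                  decay, decay_corrected=True, organ="bone")
        assert fit.lambda_bio_per_h == 0.0
        assert fit.lambda_eff_per_h == pytest.approx(math.log(2) / 159.6, rel=1e-6)
        assert fit.lambda_eff_per_h == pytest.approx(4.3434e-3, rel=1e-3)

    def test_peak_at_second_timepoint_excludes_first(self, decay):
        # hepatic pattern: uptake peaks at 24 h, first point is pre-peak
        v = np.array([8.91, 17.68, 10.43, 7.85])
        fit = fit_monoexponential(TIMES, v, decay, decay_corrected=True, organ="liver")
        assert fit.peak_time_h == 24.0
        assert fit.fit_window == (24.0, 48.0, 72.0)
        assert fit.pre_peak_points == ((4.0, 8.91),)

    def test_all_zero_series_yields_zero_fit(self, decay):
        fit = fit_monoexponential(TIMES, np.zeros(4), decay)
        assert fit.is_zero
        assert integrate(fit, decay).a_tilde_MBq_s_per_MBq == 0.0

    def test_too_few_positive_points_is_fit_error(self, decay):
        with pytest.raises(FitError):
            fit_monoexponential(TIMES, np.array([0.0, 0.0, 1.0, 0.0]), decay)

    def test_single_timepoint_rejected(self, decay):
        with pytest.raises(FitError):
            fit_monoexponential(np.array([4.0, 4.0]), np.array([1.0, 1.1]), decay)

    def test_uncorrected_fit_recovers_effective_slope(self, decay):
        lam_eff_true = 0.02
        v = 10.0 * np.exp(-lam_eff_true * TIMES)
        fit = fit_monoexponential(TIMES, v, decay, decay_corrected=False)
        assert fit.lambda_eff_per_h == pytest.approx(lam_eff_true, rel=1e-9)
        assert fit.lambda_bio_per_h == pytest.approx(
            lam_eff_true - decay.lambda_phys_per_h, rel=1e-6)


class TestIntegrate:
    def test_closed_form(self, decay):
        lam_bio = 0.01 - decay.lambda_phys_per_h  # make lambda_eff exactly 0.01
        fit = TacFit(organ="x", A0_pct_ia=10.0, lambda_bio_per_h=lam_bio,
                     lambda_phys_per_h=decay.lambda_phys_per_h)
        tia = integrate(fit, decay, peak_handling="ignore_pre_peak")
        assert tia.a_tilde_MBq_s_per_MBq == pytest.approx(36000.0, rel=1e-12)

    @pytest.mark.parametrize("peak_handling", ["ignore_pre_peak", "trapezoid_pre_peak"])
    def test_matches_quadrature_oracle(self, decay, peak_handling):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a0 = rng.uniform(0.01, 100.0)
            lam = rng.uniform(0.0, 0.1)
            tp = rng.choice([0.0, 4.0, 24.0])
            pre = ((4.0, a0 * 0.4),) if tp == 24.0 else ()
            fit = TacFit(organ="x", A0_pct_ia=a0, lambda_bio_per_h=lam,
                         lambda_phys_per_h=decay.lambda_phys_per_h,
                         peak_time_h=tp, pre_peak_points=pre)
            got = integrate(fit, decay, peak_handling).a_tilde_MBq_s_per_MBq
            want = quadrature_a_tilde(fit, peak_handling)
            assert got == pytest.approx(want, rel=1e-3)

    @given(a0=st.floats(0.0, 100.0), lam=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_physical_decay_bound(self, a0, lam):
        """a_tilde can never exceed pure physical decay of 100 %IA."""
        decay = DecayData()
        fit = TacFit(organ="x", A0_pct_ia=a0, lambda_bio_per_h=lam,
                     lambda_phys_per_h=decay.lambda_phys_per_h)
        tia = integrate(fit, decay)
        assert tia.a_tilde_MBq_s_per_MBq <= 3600.0 / decay.lambda_phys_per_h + 1e-9

    def test_trapezoid_pre_peak_reduces_early_area(self, decay):
        """Ramping up from zero before the peak gives less area than the
        back-extrapolated exponential over the same interval."""
        fit = TacFit(organ="x", A0_pct_ia=20.0, lambda_bio_per_h=0.02,
                     lambda_phys_per_h=decay.lambda_phys_per_h,
                     peak_time_h=24.0, pre_peak_points=((4.0, 5.0),))
        ig = integrate(fit, decay, "ignore_pre_peak").a_tilde_MBq_s_per_MBq
        tr = integrate(fit, decay, "trapezoid_pre_peak").a_tilde_MBq_s_per_MBq
        assert tr < ig


class TestStochasticRecovery:
    def test_lognormal_noise_bias(self, decay):
        """CV = 10%, n = 4 animals: median relative bias of lambda_bio and
        a_tilde across seeded replicates stays small."""
        from dosekit import KineticScenario, OrganKinetics, generate, summarize
        a0_true, lam_true = 10.0, 0.01
        lam_errs, at_errs = [], []
        at_true = 3600.0 * (a0_true / 100.0) / (lam_true + decay.lambda_phys_per_h)
        for seed in range(300):
            sc = KineticScenario(
                route="intratumoral",
                organs={"liver": OrganKinetics(a0_true, lam_true)},
                cv=0.10, n_animals=4, seed=seed,
            )
            s = summarize(generate(sc))
            fit = fit_monoexponential(
                s["time_h"].to_numpy(), s["mean_pct_id_per_g"].to_numpy(),
                decay, decay_corrected=True)
            tia = integrate(fit, decay)
            lam_errs.append(abs(fit.lambda_bio_per_h - lam_true) / lam_true)
            at_errs.append(abs(tia.a_tilde_MBq_s_per_MBq - at_true) / at_true)
        assert np.median(lam_errs) < 0.15
        assert np.median(at_errs) < 0.20


class TestBuildAll:
    def test_linearity_in_uptake(self, decay):
        import pandas as pd
        pts = pd.DataFrame({
            "organ": ["liver"] * 4 + ["spleen"] * 4,
            "time_h": list(TIMES) * 2,
            "pct_ia_per_organ": list(10 * np.exp(-0.02 * TIMES)) + list(np.exp(-0.01 * TIMES)),
        })
        tias1, _ = build_all_tia(pts, decay)
        doubled = pts.assign(pct_ia_per_organ=2 * pts["pct_ia_per_organ"])
        tias2, _ = build_all_tia(doubled, decay)
        for t1, t2 in zip(tias1, tias2):
            assert t2.a_tilde_MBq_s_per_MBq == pytest.approx(
                2 * t1.a_tilde_MBq_s_per_MBq, rel=1e-9)

    def test_empty_input(self, decay):
        import pandas as pd
        tias, diag = build_all_tia(
            pd.DataFrame(columns=["organ", "time_h", "pct_ia_per_organ"]), decay)
        assert tias == [] and diag.empty


class TestDecayData:
    def test_defaults(self, decay):
        assert decay.half_life_h == pytest.approx(159.6)
        assert decay.beta_branches == ((0.497, 0.78),)
        assert decay.delta_p == pytest.approx(0.208 * 0.11, rel=1e-12)
        assert decay.mean_beta_range_um == 670.0

    def test_delta_np_consistent_with_beta_spectrum(self):
        """The stored non-penetrating energy sits just above the
        yield-weighted allowed-spectrum beta mean (the gap is the
        conversion/Auger electron contribution)."""
        branches = [(0.497, 0.79), (0.384, 0.09), (0.176, 0.12)]
        beta_mean = sum(y * mean_beta_energy(emax) for emax, y in branches)
        # published mean beta energy is ~0.134 MeV
        assert beta_mean == pytest.approx(0.134, rel=0.10)
        d = DecayData()
        assert beta_mean < d.delta_np < beta_mean + 0.03

    def test_validation(self):
        with pytest.raises(ValidationError):
            DecayData(half_life_h=0.0)
        with pytest.raises(ValidationError):
            DecayData(beta_branches=((0.5, 1.5),))
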