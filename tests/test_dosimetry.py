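"""S-value generation, organ doses, sphere self-dose, effective dose."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosekit import (DecayData, EffectiveDoseWeights, OrganMassTable,
                     SphereModel, SValueMatrix, TacFit, TimeIntegratedActivity,
                     effective_dose, generate_s_matrix, organ_doses,
                     sphere_dose)
from dosekit.errors import ValidationError

MASSES = OrganMassTable(masses_g={"liver": 1910.0, "brain": 1420.0, "spleen": 183.0})


def _tia(organ: str, a_tilde: float, decay: DecayData) -> TimeIntegratedActivity:
    fit = TacFit(organ=organ, A0_pct_ia=1.0, lambda_bio_per_h=0.0,
                 lambda_phys_per_h=decay.lambda_phys_per_h)
    return TimeIntegratedActivity(organ, a_tilde, fit)


class TestSMatrix:
    def test_liver_self_s_value(self, decay):
        s = generate_s_matrix(decay, MASSES, model="local_np_only")
        # 0.147 MeV x 1.602e-13 J/MeV / 1.91 kg, per 1e6 decays, in mGy
        assert s.s("liver", "liver") == pytest.approx(1.233e-5, rel=1e-3)

    def test_local_model_has_zero_cross_terms(self, decay):
        s = generate_s_matrix(decay, MASSES, model="local_np_only")
        assert s.s("brain", "liver") == 0.0
        off = s.values.to_numpy()[~np.eye(len(s.targets), dtype=bool)]
        assert (off == 0.0).all()

    def test_halving_mass_doubles_self_s(self, decay):
        half = OrganMassTable(masses_g={"liver": 955.0})
        s1 = generate_s_matrix(decay, MASSES, model="local_np_only")
        s2 = generate_s_matrix(decay, half, model="local_np_only")
        assert s2.s("liver", "liver") == pytest.approx(2 * s1.s("liver", "liver"))

    def test_photon_model_adds_constant_bath(self, decay):
        s0 = generate_s_matrix(decay, MASSES, model="local_np_only")
        s1 = generate_s_matrix(decay, MASSES, model="local_np_plus_uniform_photon",
                               af_body=0.3)
        bath = s1.s("brain", "liver")
        assert bath > 0
        assert s1.s("liver", "liver") == pytest.approx(s0.s("liver", "liver") + bath)
        # self-dose dominates any cross term for this beta-dominated nuclide
        for t in s1.targets:
            assert s1.s(t, t) >= max(s1.s(t, src) for src in s1.sources)

    def test_missing_mass_rejected(self, decay):
        with pytest.raises(ValidationError, match="kidney"):
            generate_s_matrix(decay, MASSES, organs=["kidney"])

    def test_csv_round_trip(self, decay, tmp_path):
        s = generate_s_matrix(decay, MASSES, model="local_np_plus_uniform_photon")
        p = tmp_path / "s.csv"
        s.to_csv(p)
        again = SValueMatrix.from_csv(p)
        pd.testing.assert_frame_equal(s.values, again.values)


class TestOrganDoses:
    def test_single_product(self, decay):
        s = SValueMatrix(values=pd.DataFrame({"liver": [1.236e-5]}, index=["liver"]))
        doses = organ_doses([_tia("liver", 1.0e4, decay)], s)
        assert doses["liver"] == pytest.approx(0.1236, rel=1e-9)

    def test_zero_tias_zero_doses(self, decay):
        s = generate_s_matrix(decay, MASSES, model="local_np_only")
        doses = organ_doses([_tia("liver", 0.0, decay)], s)
        assert all(d == 0.0 for d in doses.values())

    def test_unmapped_source_rejected(self, decay):
        s = generate_s_matrix(decay, MASSES, model="local_np_only")
        with pytest.raises(ValidationError, match="kidney"):
            organ_doses([_tia("kidney", 1.0, decay)], s)

    def test_source_routing(self, decay):
        masses = OrganMassTable(masses_g={"liver": 1910.0, "total body": 73000.0})
        s = generate_s_matrix(decay, masses, model="local_np_only")
        doses = organ_doses([_tia("blood", 1.0e4, decay)], s,
                            source_routing={"blood": "total body"})
        assert doses["total body"] > 0
        assert doses["liver"] == 0.0

    @given(c=st.floats(min_value=0.0, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_a_tilde(self, c):
        decay = DecayData()
        s = generate_s_matrix(decay, MASSES, model="local_np_plus_uniform_photon")
        tias = [_tia("liver", 2.0e4, decay), _tia("spleen", 3.0e3, decay)]
        scaled = [_tia(t.organ, c * t.a_tilde_MBq_s_per_MBq, decay) for t in tias]
        base, got = organ_doses(tias, s), organ_doses(scaled, s)
        for organ in base:
            assert got[organ] == pytest.approx(c * base[organ], rel=1e-9, abs=1e-300)


class TestSphere:
    def test_edge_loss_absorbed_fraction(self, decay):
        m = SphereModel(sphere_mass_g=0.5)
        # R ~ 4.92 mm against a 670 um mean beta range
        assert m.radius_cm == pytest.approx(0.4924, abs=1e-3)
        assert m.phi_np(decay) >= 0.89
        assert SphereModel(sphere_mass_g=1e3).phi_np(decay) > 0.99
        assert SphereModel(sphere_mass_g=1e9).phi_np(decay) == pytest.approx(1.0, abs=1e-3)

    def test_zero_a_tilde_zero_dose(self, decay):
        assert sphere_dose(0.0, decay, 0.5) == 0.0

    def test_dose_arithmetic_against_definition(self, decay):
        a_tilde, mass = 42.0, 0.5
        model = SphereModel(sphere_mass_g=mass, phi_p=0.03)
        e_mev = decay.delta_np * model.phi_np(decay) + decay.delta_p * 0.03
        want = a_tilde * e_mev * 1.602176634e-13 / (mass / 1000.0) * 1e9
        assert sphere_dose(a_tilde, decay, mass) == pytest.approx(want, rel=1e-12)

    def test_dose_decreases_with_mass(self, decay):
        d1 = sphere_dose(100.0, decay, 0.5)
        d2 = sphere_dose(100.0, decay, 1.0)
        assert d2 < d1
        # at fixed phi values the dependence is exactly 1/mass
        ratio_phi = (SphereModel(1.0).phi_np(decay) * decay.delta_np + 0.03 * decay.delta_p) / (
            SphereModel(0.5).phi_np(decay) * decay.delta_np + 0.03 * decay.delta_p)
        assert d2 == pytest.approx(d1 / 2.0 * ratio_phi, rel=1e-9)

    def test_nonpositive_mass_rejected(self, decay):
        with pytest.raises(ValidationError):
            sphere_dose(1.0, decay, 0.0)


class TestEffectiveDose:
    def test_uniform_doses_recover_d(self):
        w = EffectiveDoseWeights.icrp60()
        organs = ["testes", "bone marrow", "large intestine", "lung", "stomach",
                  "urinary bladder wall", "breasts", "liver", "esophagus",
                  "thyroid", "skin", "bone", "kidney", "brain"]
        d = 0.42
        assert effective_dose({o: d for o in organs}, w) == pytest.approx(d, rel=1e-9)

    def test_zero_doses(self):
        assert effective_dose({}, EffectiveDoseWeights.icrp60()) == 0.0

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            EffectiveDoseWeights(weights={"liver": 0.5})

    def test_missing_weighted_tissue_uses_zero(self, caplog):
        import logging
        w = EffectiveDoseWeights.icrp60()
        with caplog.at_level(logging.WARNING, logger="dosekit.dosimetry"):
            val = effective_dose({"liver": 1.0}, w)
        assert 0 < val < 1.0
        assert any("esophagus" in r.getMessage() for r in caplog.records)
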