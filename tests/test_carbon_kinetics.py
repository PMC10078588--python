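"""Reaction-rate functions: values, limits, homogeneity, closure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltacarbon.carbon_kinetics import (BoxState, KineticParams,
                                         flocculation_rate, hydrolysis_rate,
                                         iss_settling_velocity,
                                         microbial_degradation_rate,
                                         phyto_rates, resuspension_flux,
                                         settling_flux, temp_factor)


class TestTempFactor:
    def test_unity_at_reference(self):
        assert temp_factor(20.0, 0.069, 20.0) == 1.0

    def test_q10_of_two(self):
        assert temp_factor(30.0, 0.069, 20.0) == pytest.approx(
            np.exp(0.69), rel=1e-12)
        assert temp_factor(30.0, 0.069, 20.0) == pytest.approx(1.9937, abs=2e-4)

    def test_strictly_increasing(self):
        t = np.linspace(-2.0, 30.0, 50)
        assert np.all(np.diff(temp_factor(t, 0.069, 20.0)) > 0)


class TestMicrobialDegradation:
    def test_labile_rate_at_reference_temperature(self, params):
        rate = microbial_degradation_rate(1.0, 0, 20.0, params)
        assert rate == pytest.approx(0.025, rel=1e-12)

    def test_refractory_e_folding_time(self, params):
        # 0.001 d-1 refractory rate -> 1000-day e-folding
        rate = microbial_degradation_rate(1.0, 2, 20.0, params)
        assert 1.0 / rate == pytest.approx(1000.0, rel=1e-12)

    def test_switched_off(self, params):
        off = params.with_overrides(kappa_c=(0.0, 0.0, 0.0))
        assert microbial_degradation_rate(5.0, 0, 25.0, off) == 0.0

    def test_unknown_class_rejected(self, params):
        with pytest.raises(KeyError):
            microbial_degradation_rate(1.0, 7, 20.0, params)


class TestHydrolysis:
    @pytest.mark.parametrize("class_index, half_life",
                             [(0, 23.1), (1, 115.5)])
    def test_half_lives(self, params, class_index, half_life):
        rate = hydrolysis_rate(1.0, class_index, 20.0, params)
        assert np.log(2.0) / rate == pytest.approx(half_life, abs=0.1)

    def test_zero_concentration(self, params):
        assert hydrolysis_rate(0.0, 0, 25.0, params) == 0.0


class TestFlocculation:
    @pytest.fixture
    def floc_params(self, params):
        return params.with_overrides(kappa_fmax=0.1)

    def test_peak_at_optimal_salinity(self, floc_params):
        assert flocculation_rate(1.0, floc_params) == pytest.approx(0.1)

    def test_freshwater_value(self, floc_params):
        # 0.1 * exp(-5 * (0 - 1)^2)
        assert flocculation_rate(0.0, floc_params) == pytest.approx(
            0.1 * np.exp(-5.0), rel=1e-12)

    def test_super_optimal_value(self, floc_params):
        # 0.1 * exp(-0.25 * (1 - 2)^2)
        assert flocculation_rate(2.0, floc_params) == pytest.approx(
            0.1 * np.exp(-0.25), rel=1e-12)

    def test_curve_continuous_with_maximum_at_s_max(self, floc_params):
        s = np.arange(0.0, 30.0, 1e-3)
        kf = flocculation_rate(s, floc_params)
        assert kf.max() == pytest.approx(0.1, rel=1e-9)
        assert abs(s[np.argmax(kf)] - 1.0) < 2e-3
        assert np.all(np.abs(np.diff(kf)) < 1e-3)  # no jump at the junction

    def test_zero_rate_in_baseline(self, params):
        assert np.all(flocculation_rate(np.array([0.0, 1.0, 5.0]), params)
                      == 0.0)


class TestSettling:
    def test_iss_velocity_limits(self, params):
        assert iss_settling_velocity(0.0, params) == 0.0
        assert iss_settling_velocity(51.0, params) == pytest.approx(1.0)
        assert iss_settling_velocity(1e9, params) == pytest.approx(2.0, rel=1e-6)

    def test_iss_velocity_monotone(self, params):
        c = np.linspace(0.0, 500.0, 100)
        assert np.all(np.diff(iss_settling_velocity(c, params)) > 0)

    def test_uniform_column_interior_tendency_zero(self):
        assert settling_flux(3.0, 3.0, 1.0, 0.5) == 0.0

    def test_no_settling_scenario(self):
        assert settling_flux(5.0, 1.0, 0.0, 1.0) == 0.0

    def test_column_integral_telescopes_to_bottom_export(self):
        """Sum of layer tendencies x dz equals -w * C_bottom (oracle)."""
        rng = np.random.default_rng(3)
        conc = rng.uniform(0.0, 10.0, 8)
        w, dz = 0.8, 1.25
        above = np.concatenate([[0.0], conc[:-1]])
        tendencies = settling_flux(above, conc, w, dz)
        assert tendencies.sum() * dz == pytest.approx(-w * conc[-1], rel=1e-12)


class TestResuspension:
    def test_threshold_boundary_and_below(self, params):
        assert resuspension_flux(0.005, params) == 0.0
        assert resuspension_flux(0.004, params) == 0.0

    def test_linear_excess_stress(self, params):
        assert resuspension_flux(0.015, params) == pytest.approx(
            1.0e-7, rel=1e-12)


class TestPhytoRates:
    def test_dark_limit(self, params):
        r = phyto_rates(1.0, 1.0, 0.0, 20.0, 0, params)
        assert r["growth"] == 0.0
        assert r["predation"] == pytest.approx(1.5)

    def test_exudation_fraction(self, params):
        r = phyto_rates(1.0, 1e9, 1e9, 20.0, 0, params)
        assert r["exudation"] == pytest.approx(0.2 * r["growth"], rel=1e-12)

    def test_predation_and_poc_production(self, params):
        r = phyto_rates(1.0, 0.0, 0.0, 20.0, 0, params)
        assert r["predation"] == pytest.approx(1.5, rel=1e-12)
        assert r["poc_production"][0] == pytest.approx(0.15, rel=1e-12)
        assert r["poc_production"][1] == pytest.approx(0.75, rel=1e-12)

    def test_predation_remainder_closes(self, params):
        r = phyto_rates(2.0, 1.0, 50.0, 15.0, 1, params)
        routed = (sum(r["poc_production"]) + r["predation_to_ncdoc1"]
                  + r["predation_to_co2"])
        assert routed == pytest.approx(r["predation"], rel=1e-12)


class TestStateAndParams:
    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            BoxState(cdoc_w=-0.1)

    def test_poc_fractions_must_not_exceed_unity(self):
        with pytest.raises(ValueError):
            KineticParams(f_b=(0.7, 0.6), predation_to_ncdoc1=-0.15,
                          predation_to_co2=-0.15)

    def test_table_defaults(self, params):
        assert params.kappa_c == (0.025, 0.01, 0.001)
        assert params.kappa_p == (0.03, 0.006)
        assert params.w_p == (1.0, 0.4)
        assert (params.s_max, params.kappa_c1, params.kappa_c2) == (1.0, 5.0, 0.25)
        assert (params.tau_crit, params.m_tau) == (0.005, 1.0e-5)


@settings(max_examples=50, deadline=None)
@given(conc=st.floats(0.0, 100.0), scale=st.floats(0.1, 10.0),
       t=st.floats(-2.0, 30.0))
def test_first_order_rates_are_homogeneous_degree_one(conc, scale, t):
    p = KineticParams()
    for fn, idx in ((microbial_degradation_rate, 1), (hydrolysis_rate, 0)):
        base = fn(conc, idx, t, p)
        assert fn(scale * conc, idx, t, p) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-12)
        assert base >= 0.0


@settings(max_examples=50, deadline=None)
@given(b=st.floats(0.0, 50.0), scale=st.floats(0.1, 10.0))
def test_predation_is_homogeneous_degree_two(b, scale):
    p = KineticParams()
    base = phyto_rates(b, 1.0, 100.0, 20.0, 0, p)["predation"]
    scaled = phyto_rates(scale * b, 1.0, 100.0, 20.0, 0, p)["predation"]
    assert scaled == pytest.approx(scale ** 2 * base, rel=1e-9, abs=1e-12)


def test_instantaneous_carbon_tendencies_sum_to_zero():
    """Term-by-term oracle: on random states, production and loss terms
    (including the CO2 and deposition sinks as ledger entries) cancel."""
    rng = np.random.default_rng(42)
    p = KineticParams()
    for _ in range(20):
        doc = rng.uniform(0.0, 10.0, 6)     # per lability mapping order
        poc = rng.uniform(0.0, 5.0, 2)
        b = rng.uniform(0.0, 2.0, 2)
        t, s, par, din = (rng.uniform(0, 25), rng.uniform(0, 30),
                          rng.uniform(0, 300), rng.uniform(0, 1))
        kf = float(flocculation_rate(s, p.with_overrides(kappa_fmax=0.1)))
        tends = {"co2": 0.0}
        labilities = [p.doc_lability[v] for v in
                      ("cdoc_m", "cdoc_w", "cdoc_ss", "ncdoc1", "ncdoc2",
                       "ncdoc3")]
        doc_tend = np.zeros(6)
        for j, lab in enumerate(labilities):
            loss = microbial_degradation_rate(doc[j], lab, t, p)
            doc_tend[j] -= loss
            tends["co2"] += loss
        floc_loss = kf * doc[1] + kf * doc[2]   # riverine CDOC classes
        doc_tend[1] -= kf * doc[1]
        doc_tend[2] -= kf * doc[2]
        poc_tend = np.array([0.0, floc_loss])
        hyd = [hydrolysis_rate(poc[k], k, t, p) for k in range(2)]
        poc_tend -= np.array(hyd)
        doc_tend[3] += hyd[0]
        doc_tend[5] += hyd[1]
        b_tend = np.zeros(2)
        npp = 0.0
        for g in range(2):
            r = phyto_rates(b[g], din, par, t, g, p)
            b_tend[g] += (r["growth"] - r["exudation"]) - r["predation"]
            doc_tend[0] += r["exudation"]
            poc_tend += np.array(r["poc_production"])
            doc_tend[3] += r["predation_to_ncdoc1"]
            tends["co2"] += r["predation_to_co2"]
            npp += r["growth"]
        total = doc_tend.sum() + poc_tend.sum() + b_tend.sum() \
            + tends["co2"] - npp
        scale = abs(npp) + abs(tends["co2"]) + np.abs(doc_tend).sum() + 1.0
        assert abs(total) / scale < 1e-12
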