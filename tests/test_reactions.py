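"""Reaction network: Monod kinetics, rate tying, calcite, solid phases."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hyporheic as hp
from hyporheic.reactions import (MU_AER_RANGE, MU_NIT_RANGE, CalciteKinetics,
                                 MonodReaction, SolidPhases,
                                 nsom_ammonification_rate)


def simple_rxn(**kw) -> MonodReaction:
    args = dict(name="aer", mu_max=1e-3, substrate="acetate", K_S=1e-4,
                tea="o2", K_TEA=1e-5,
                stoichiometry={"acetate": -1.0, "o2": -2.0, "hco3": 2.0,
                               "h+": 1.0})
    args.update(kw)
    return MonodReaction(**args)


class TestMonodRate:
    def test_half_saturation_quarter_rate(self):
        rxn = simple_rxn()
        rate = hp.monod_rate(rxn, {"acetate": 1e-4, "o2": 1e-5})
        assert rate == pytest.approx(1e-3 * 1e-5 / 4, rel=1e-12)

    def test_inhibited_eighth_rate(self):
        rxn = simple_rxn(name="den", substrate="acetate", tea="no3",
                         K_TEA=1e-5, inhibitor="o2", K_I=1e-6,
                         stoichiometry={"acetate": -1.0, "no3": -1.6,
                                        "h+": -0.6, "hco3": 2.0, "n2": 0.8,
                                        "h2o": 0.8})
        rate = hp.monod_rate(rxn, {"acetate": 1e-4, "no3": 1e-5, "o2": 1e-6})
        assert rate == pytest.approx(1e-3 * 1e-5 / 8, rel=1e-12)
        assert rate == pytest.approx(1.25e-9, rel=1e-9)

    def test_saturating_limit(self):
        rxn = simple_rxn()
        rate = hp.monod_rate(rxn, {"acetate": 10.0, "o2": 10.0})
        assert rate == pytest.approx(1e-3 * 1e-5, rel=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hp.monod_rate(simple_rxn(), {"acetate": -1e-9, "o2": 1e-5})

    def test_rate_vanishes_with_reactants(self):
        rxn = simple_rxn()
        assert hp.monod_rate(rxn, {"acetate": 0.0, "o2": 1e-4}) == 0.0
        assert hp.monod_rate(rxn, {"acetate": 1e-4, "o2": 0.0}) == 0.0

    @given(o2=st.floats(0.0, 1e-3))
    @settings(max_examples=25, deadline=None)
    def test_denitrification_decreasing_nitrification_increasing_in_o2(self, o2):
        net = hp.default_network()
        conc = {"acetate": 1e-4, "no3": 1e-5, "nh4": 1e-6, "o2": o2}
        conc_hi = dict(conc, o2=o2 + 1e-6)
        assert (hp.monod_rate(net.denitrification, conc_hi)
                <= hp.monod_rate(net.denitrification, conc))
        assert (hp.monod_rate(net.nitrification, conc_hi)
                >= hp.monod_rate(net.nitrification, conc))


class TestRateTying:
    def test_printed_monte_carlo_range_endpoints(self):
        # the published aerobic and nitrification ranges share ratio 0.36
        assert hp.tie_nitrification_rate(1.30e-4, -800.0, -288.0) == \
            pytest.approx(4.68e-5, rel=1e-9)
        # upper ends agree to their printed two significant figures
        assert hp.tie_nitrification_rate(2.01e-3, -800.0, -288.0) == \
            pytest.approx(7.26e-4, rel=5e-3)
        assert MU_NIT_RANGE[0] / MU_AER_RANGE[0] == pytest.approx(0.36, abs=1e-9)

    def test_equal_energies_equal_rates(self):
        assert hp.tie_nitrification_rate(5e-4, -500.0, -500.0) == 5e-4

    def test_zero_or_mixed_sign_energy_rejected(self):
        with pytest.raises(ValueError):
            hp.tie_nitrification_rate(1e-4, 0.0, -288.0)
        with pytest.raises(ValueError):
            hp.tie_nitrification_rate(1e-4, -800.0, 288.0)

    def test_aerobic_preference(self):
        net = hp.default_network()
        assert net.nitrification.mu_max < net.aerobic.mu_max

    def test_network_enforces_tie(self):
        net = hp.default_network()
        bad_nit = net.nitrification.with_mu(net.nitrification.mu_max * 1.5)
        with pytest.raises(ValueError):
            dataclasses.replace(net, nitrification=bad_nit)

    @given(mu=st.floats(*MU_AER_RANGE))
    @settings(max_examples=25, deadline=None)
    def test_ratio_preserved_under_rate_updates(self, mu):
        net = hp.default_network().with_rates(mu_aer=mu)
        assert net.nitrification.mu_max / net.aerobic.mu_max == \
            pytest.approx(net.dG_nit / net.dG_aer, rel=1e-12)


class TestCalcite:
    def test_zero_at_equilibrium(self):
        kin = CalciteKinetics()
        assert hp.calcite_rate(kin, 1e-8, 1e-3, kin.k_eq) == pytest.approx(0.0)

    def test_zero_constants_zero_rate(self):
        kin = CalciteKinetics(k_neutral=0, k_proton=0, k_bicarbonate=0)
        assert hp.calcite_rate(kin, 1e-8, 1e-3, kin.k_eq * 0.5) == 0.0

    def test_plug_in_arithmetic(self):
        kin = CalciteKinetics(surface_area=1.0, k_neutral=1e-8, k_proton=0.0,
                              k_bicarbonate=0.0)
        rate = hp.calcite_rate(kin, 1e-8, 1e-3, kin.k_eq * 0.5)
        assert abs(rate) == pytest.approx(5e-9, rel=1e-12)
        assert rate < 0    # undersaturated -> dissolution (negative)

    def test_dissolution_suppressed_when_exhausted(self):
        kin = CalciteKinetics()
        rate = hp.calcite_rate(kin, 1e-8, 1e-3, kin.k_eq * 0.5,
                               mineral_amount=0.0)
        assert rate == 0.0


class TestSolidPhases:
    def test_nsom_rate_and_exhaustion(self):
        s = SolidPhases(nsom_rate=4e-10, nsom_n_stoich=1.0)
        assert nsom_ammonification_rate(s) == pytest.approx(4e-10)
        assert nsom_ammonification_rate(s, nsom_amount=0.0) == 0.0

    def test_nsom_released_moles_over_time(self):
        # integrating the constant source over dt in one cell
        s = SolidPhases(nsom_rate=4e-10, nsom_n_stoich=1.0)
        geom = hp.FlowPathGeometry(10.0)
        dt = 3600.0
        released = nsom_ammonification_rate(s) * dt * (geom.dx_m * 1.0 * 1.0)
        assert released == pytest.approx(4e-10 * 3600 * 0.1, rel=1e-12)

    def test_acetate_equilibrium_restores_exactly(self):
        s = SolidPhases(som_amount=10.0, acetate_eq=1e-4)
        ace, som = hp.acetate_equilibrium(s, 1e-4 - 1e-5)
        assert ace == pytest.approx(1e-4, rel=1e-12)
        assert som == pytest.approx(10.0 - 1e-5 * 200.0, rel=1e-12)

    def test_acetate_equilibrium_noop_at_setpoint(self):
        s = SolidPhases(som_amount=10.0, acetate_eq=1e-4)
        ace, som = hp.acetate_equilibrium(s, 1e-4)
        assert ace == 1e-4 and som == 10.0

    def test_acetate_free_to_deplete_without_som(self):
        s = SolidPhases(som_amount=0.0, acetate_eq=1e-4)
        ace, som = hp.acetate_equilibrium(s, 5e-5, som_amount=0.0)
        assert ace == pytest.approx(5e-5)
        assert som == 0.0


class TestOverallDOConsumption:
    def test_zero_oxygen_zero_rate(self):
        net = hp.default_network()
        conc = {"o2": 0.0, "acetate": 1e-4, "nh4": 1e-6, "no3": 1e-5}
        assert hp.overall_DO_consumption(conc, net) == 0.0

    def test_reduces_to_aerobic_term_without_ammonium(self):
        net = hp.default_network()
        conc = {"o2": 2e-4, "acetate": 1e-4, "nh4": 0.0, "no3": 1e-5}
        expected = 2.0 * hp.monod_rate(net.aerobic, conc)
        assert hp.overall_DO_consumption(conc, net) == pytest.approx(
            expected, rel=1e-12)

    def test_half_saturation_plug_in(self):
        net = hp.default_network()
        conc = {"acetate": net.aerobic.K_S, "o2": net.aerobic.K_TEA,
                "nh4": net.nitrification.K_S, "no3": 1e-5}
        # both reactions share K_TEA for O2 here, so each term is muX/4
        expected = (2 * net.aerobic.mu_max + 2 * net.nitrification.mu_max) \
            * net.aerobic.X_im / 4
        assert hp.overall_DO_consumption(conc, net) == pytest.approx(
            expected, rel=1e-12)

    def test_increasing_in_oxygen(self):
        net = hp.default_network()
        o2s = np.linspace(0, 5e-4, 40)
        rates = [hp.overall_DO_consumption(
            {"o2": o, "acetate": 1e-4, "nh4": 1e-6, "no3": 1e-5}, net)
            for o in o2s]
        assert np.all(np.diff(rates) > 0)


class TestStoichiometryValidation:
    def test_default_network_balances(self):
        hp.default_network()    # construction runs element/charge checks

    def test_unbalanced_stoichiometry_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            simple_rxn(stoichiometry={"acetate": -1.0, "o2": -2.0,
                                      "hco3": 1.0, "h+": 1.0})

    def test_charge_imbalance_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            simple_rxn(stoichiometry={"acetate": -1.0, "o2": -2.0,
                                      "hco3": 2.0})
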