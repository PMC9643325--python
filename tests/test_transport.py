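"""Transport stepper: advection, reaction limits, spin-up, transients."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

import hyporheic as hp
from hyporheic.flow import velocity_from_gradient
from hyporheic.reactions import SolidPhases
from hyporheic.transport import (SPECIES, new_state, run_transient, spin_up,
                                 steady_profile, step)

I_O2 = SPECIES.index("o2")
I_TR = SPECIES.index("tracer")


def quiet_network(mu_aer, K_S=1e-12, K_TEA=1e-5, mu_den=1e-30):
    """Single effective O2 sink: aerobic respiration with pinned factors.

    K_S ~ 0 keeps the substrate factor at 1; N-SOM dissolution is off so
    nitrification stays silent when ammonium is zero.
    """
    net = hp.default_network(mu_aer=mu_aer, mu_den=mu_den,
                             solids=SolidPhases(nsom_rate=0.0))
    aer = dataclasses.replace(net.aerobic, K_S=K_S, K_TEA=K_TEA)
    return dataclasses.replace(net, aerobic=aer)


class TestAdvection:
    def test_tracer_pulse_translates_and_conserves_mass(self):
        geom = hp.FlowPathGeometry(58.0)
        model = hp.FlowPathModel(geometry=geom, inert=True)
        state = new_state(model)
        state.conc[:] = 0.0
        cells = np.arange(geom.n_cells)
        state.conc[I_TR] = np.exp(-0.5 * ((cells - 100) * geom.dx_m / 1.5) ** 2)
        model = dataclasses.replace(model,
                                    chemistry=hp.BoundaryChemistry(
                                        o2=0, no3=0, nh4=0, acetate=0, ca=0,
                                        dic=0, tracer=0))
        m0 = state.conc[I_TR].sum()
        com0 = np.sum(cells * state.conc[I_TR]) / m0 * geom.dx_m
        v = 2.0e-5
        hours = 200
        for _ in range(hours):
            state = step(model, state, v, 1.0)
        m1 = state.conc[I_TR].sum()
        com1 = np.sum(cells * state.conc[I_TR]) / m1 * geom.dx_m
        assert m1 == pytest.approx(m0, rel=1e-3)           # < 0.1 %
        assert com1 - com0 == pytest.approx(v * hours * 3600, abs=2 * geom.dx_m)

    def test_zero_velocity_is_identity_for_inert_model(self):
        model = hp.FlowPathModel(geometry=hp.FlowPathGeometry(10.0), inert=True)
        state = new_state(model)
        out = step(model, state, 0.0, 1.0)
        assert np.array_equal(out.conc, state.conc)

    def test_oversized_dt_rejected(self):
        model = hp.FlowPathModel(geometry=hp.FlowPathGeometry(10.0))
        with pytest.raises(ValueError):
            step(model, new_state(model), 1e-5, 2.0)


class TestReactionLimits:
    def test_static_monod_decay_matches_analytic_solution(self):
        """v = 0: O2 decay follows the closed-form Monod ODE solution.

        K ln(C0/C) + (C0 - C) = a t with a the (constant) saturated rate;
        the half-saturation K spans both the zeroth-order and the
        first-order (C << K_TEA) regimes of the decay.
        """
        mu = 1.0e-3
        net = quiet_network(mu_aer=mu, K_TEA=1e-5)
        model = hp.FlowPathModel(geometry=hp.FlowPathGeometry(5.0),
                                 network=net,
                                 chemistry=hp.BoundaryChemistry(nh4=0.0))
        a = 2.0 * mu * net.aerobic.X_im      # mol O2 / (L s)
        K, C0 = 1e-5, model.chemistry.o2
        state = new_state(model)
        for hour in range(1, 5):
            state = step(model, state, 0.0, 1.0)
            t = hour * 3600.0

            def implicit(c):
                return K * np.log(C0 / c) + (C0 - c) - a * t
            expected = brentq(implicit, 1e-30, C0, xtol=1e-30, rtol=1e-14)
            got = state.conc[I_O2]
            assert np.all(np.abs(got - expected) <= 1e-6 * expected)

    def test_zeroth_order_steady_profile_linear_with_known_extinction(self):
        """Steady advection against a constant sink: linear O2 ramp.

        The fitted slope must equal -r/v and its zero crossing v*C0/r.
        """
        g = 0.0065
        geom = hp.FlowPathGeometry(58.0)
        v = float(velocity_from_gradient(g, geom))
        C0 = 2.5e-4
        x_e_target = 30.0
        r = v * C0 / x_e_target                  # mol/(L s) O2 sink
        net = quiet_network(mu_aer=r / (2 * 1e-5), K_TEA=1e-12)
        model = hp.FlowPathModel(geometry=geom, network=net)
        res = spin_up(model, g, hours=4000)
        o2 = res.state.conc[I_O2]
        x = geom.x_centers
        core = (x > 2.0) & (x < x_e_target - 3.0)
        slope, intercept = np.polyfit(x[core], o2[core], 1)
        assert slope == pytest.approx(-r / v, rel=0.01)
        assert -intercept / slope == pytest.approx(x_e_target, rel=0.01)
        # the profile really is linear in the core region
        resid = o2[core] - (slope * x[core] + intercept)
        assert np.max(np.abs(resid)) < 0.01 * C0


class TestSpinUp:
    def test_unique_steady_state_from_different_initials(self, model10):
        g = 0.017
        a = spin_up(model10, g, hours=2500,
                    initial=new_state(model10, fill="boundary"))
        b = spin_up(model10, g, hours=2500,
                    initial=new_state(model10, fill="zero"))
        assert np.allclose(a.state.conc, b.state.conc, rtol=1e-6, atol=1e-12)

    def test_zero_boundary_chemistry_zero_field(self):
        chem = hp.BoundaryChemistry(o2=0, no3=0, nh4=0, acetate=0, ca=0,
                                    dic=0, tracer=0)
        net = hp.default_network(solids=SolidPhases(
            som_amount=0.0, acetate_eq=0.0, nsom_rate=0.0, calcite_amount=0.0))
        model = hp.FlowPathModel(geometry=hp.FlowPathGeometry(10.0),
                                 network=net, chemistry=chem)
        res = spin_up(model, 0.01, hours=400)
        assert np.max(np.abs(res.state.conc)) < 1e-20

    def test_longer_spin_up_changes_nothing(self, model10):
        res = spin_up(model10, 0.017, hours=2500)
        more = spin_up(model10, 0.017, hours=200, initial=res.state)
        denom = np.maximum(np.abs(res.state.conc), 1e-12)
        assert np.max(np.abs(more.state.conc - res.state.conc) / denom) < 1e-6

    def test_steadiness_metric_reported(self, model10):
        res = spin_up(model10, 0.017, hours=2500)
        assert res.steadiness < 1e-10


class TestTransient:
    @staticmethod
    def const_heads(gradient, L, days):
        t = np.arange(0.0, days * 24.0 + 0.5)
        return hp.HeadSeries(t, np.full_like(t, 10.0 + gradient * L),
                             np.full_like(t, 10.0), L)

    def test_constant_heads_hold_the_steady_state(self, model10):
        g = 0.017
        base = spin_up(model10, g, hours=2500)
        heads = self.const_heads(g, 10.0, days=5)
        traj = run_transient(model10, heads, base.state)
        denom = np.maximum(np.abs(base.state.conc), 1e-15)
        drift = np.max(np.abs(traj.state1.conc - base.state.conc) / denom)
        assert drift < 1e-6

    def test_gradient_step_expands_o2_penetration_monotonically(self, model10):
        g_lo, g_hi = 0.005, 0.012
        base = spin_up(model10, g_lo, hours=2500)
        heads = self.const_heads(g_hi, 10.0, days=12)
        traj = run_transient(model10, heads, base.state)
        thresh = 0.5 * model10.chemistry.o2

        def penetration(snap):
            below = np.nonzero(snap[I_O2] < thresh)[0]
            return model10.geometry.x_centers[below[0]] if below.size \
                else model10.geometry.length_m
        depths = [penetration(s) for s in traj.snapshots]
        assert np.all(np.diff(depths) >= -model10.geometry.dx_m)
        assert depths[-1] > depths[0]
        # approaches the quasi-steady extent at the higher gradient
        target = penetration(spin_up(model10, g_hi, hours=2500).state.conc)
        assert depths[-1] == pytest.approx(target, abs=3 * model10.geometry.dx_m)

    def test_tracer_conservation_through_transient(self):
        geom = hp.FlowPathGeometry(10.0)
        chem = hp.BoundaryChemistry(tracer=1e-4)
        model = hp.FlowPathModel(geometry=geom, chemistry=chem, inert=True)
        state = new_state(model)
        state.conc[I_TR] = 0.0    # empty of tracer, boundary feeds it in
        t = np.arange(0.0, 20 * 24.0 + 0.5)
        g = 0.012 + 0.006 * np.sin(t / 50.0)
        heads = hp.HeadSeries(t, 10.0 + g * 10.0, np.full_like(t, 10.0), 10.0)
        traj = run_transient(model, heads, state)
        influx = traj.cum_influx[I_TR]
        outflux = traj.cum_outflux[I_TR]
        storage = (traj.state1.conc[I_TR].sum()
                   - traj.state0.conc[I_TR].sum()) * geom.cell_water_volume_L
        assert influx - outflux == pytest.approx(storage, rel=1e-3)
        # the hourly flux series agrees with the exact accumulation closely
        q = np.abs(traj.velocity) * geom.porosity * 1000.0
        series_influx = np.trapezoid(q * traj.c_in[I_TR], traj.times_h * 3600.0)
        assert series_influx == pytest.approx(influx, rel=1e-3)


class TestSteadyProfileCrossCheck:
    def test_continuum_profile_matches_marched_state(self, model10):
        """Travel-time ODE vs upwind-marched steady state (independent routes)."""
        g = 0.017
        marched = spin_up(model10, g, hours=2500).state.conc
        continuum = steady_profile(model10, g)
        # O2 fields agree within the upwind scheme's numerical diffusion
        scale = model10.chemistry.o2
        assert np.max(np.abs(marched[I_O2] - continuum[I_O2])) < 0.05 * scale

    def test_grid_refinement_preserves_aerobic_extent(self):
        from hyporheic.damkohler import damkohler_profile
        crossings = []
        for dx in (0.1, 0.05):
            geom = hp.FlowPathGeometry(10.0, dx_m=dx)
            model = hp.FlowPathModel(geometry=geom)
            res = spin_up(model, 0.017, hours=2500)
            v = float(velocity_from_gradient(0.017, geom))
            da = damkohler_profile(res.state, v, geom, model.network)
            crossings.append(da.crossing_m)
        assert crossings[1] == pytest.approx(crossings[0], rel=0.05)


class TestIntegratorEquivalence:
    def test_numba_and_numpy_reaction_updates_agree(self, model10):
        import hyporheic.transport as tr
        if not tr._NUMBA:
            pytest.skip("numba unavailable; single implementation in use")
        state = new_state(model10)
        st1 = step(model10, state, 1.5e-5, 1.0)
        try:
            tr._NUMBA = False
            st2 = step(model10, state, 1.5e-5, 1.0)
        finally:
            tr._NUMBA = True
        assert np.allclose(st1.conc, st2.conc, rtol=1e-9, atol=1e-20)
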