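"""Shared fixtures: study-season models and the expensive season runs.

The heavy transient simulations (full 207 d / 168 d seasons on the 58 m
path) are session-scoped and shared between the budget-level unit tests
and the acceptance suite.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

import hyporheic as hp
from hyporheic.budget import boundary_fluxes
from hyporheic.transport import run_transient, spin_up


@pytest.fixture(scope="session")
def model58() -> hp.FlowPathModel:
    return hp.FlowPathModel(geometry=hp.FlowPathGeometry(58.0))


@pytest.fixture(scope="session")
def model10() -> hp.FlowPathModel:
    return hp.FlowPathModel(geometry=hp.FlowPathGeometry(10.0))


@pytest.fixture(scope="session")
def scenario18() -> hp.SeasonScenario:
    return hp.scenario_2018()


@pytest.fixture(scope="session")
def heads18(scenario18) -> hp.HeadSeries:
    return hp.generate_season(scenario18)


@pytest.fixture(scope="session")
def heads18_nodam(scenario18, heads18) -> hp.HeadSeries:
    window = (scenario18.day_of(scenario18.dam_build_start) * 24.0,
              scenario18.day_of(scenario18.dam_destroy) * 24.0)
    return hp.make_no_dam_counterfactual(heads18, window)


@pytest.fixture(scope="session")
def heads19() -> hp.HeadSeries:
    return hp.generate_season(hp.scenario_2019())


@pytest.fixture(scope="session")
def compressed_scenario() -> hp.SeasonScenario:
    """A short synthetic season (60 d) with the same gradient extremes.

    Used by the ensemble analyses so the sweep and Morris runs finish in
    minutes while preserving snowmelt peak, recession, and a dam episode
    occupying about a third of the window, as in the study season.
    """
    return hp.SeasonScenario(
        season_start=date(2018, 6, 1), season_end=date(2018, 7, 31),
        start_gradient=0.0066, snowmelt_peak_day=12.0,
        snowmelt_peak_gradient=0.0073, recession_tau_days=8.0,
        baseflow_gradient=0.0056,
        dam_build_start=date(2018, 7, 1), dam_build_end=date(2018, 7, 20),
        dam_destroy=date(2018, 7, 21), dam_peak_gradient=0.017)


@pytest.fixture(scope="session")
def compressed_heads(compressed_scenario) -> hp.HeadSeries:
    return hp.generate_season(compressed_scenario)


@pytest.fixture(scope="session")
def compressed_heads_nodam(compressed_scenario, compressed_heads) -> hp.HeadSeries:
    sc = compressed_scenario
    window = (sc.day_of(sc.dam_build_start) * 24.0,
              sc.day_of(sc.dam_destroy) * 24.0)
    return hp.make_no_dam_counterfactual(compressed_heads, window)


@pytest.fixture(scope="session")
def season_runs(model58, heads18, heads18_nodam, heads19):
    """Trajectories for the dam / no-dam / 2019 / steady scenarios."""
    g_ss = hp.steady_baseline_gradient(heads18, heads19)
    base18 = spin_up(model58, float(heads18.gradient[0]))
    base19 = spin_up(model58, float(heads19.gradient[0]))
    base_ss = spin_up(model58, g_ss)
    L = model58.geometry.length_m
    heads_ss = hp.HeadSeries(
        heads18.times_h, np.full_like(heads18.times_h, 10.0 + L * g_ss),
        np.full_like(heads18.times_h, 10.0), L)
    runs = {
        "dam": run_transient(model58, heads18, base18.state),
        "nodam": run_transient(model58, heads18_nodam, base18.state),
        "y2019": run_transient(model58, heads19, base19.state),
        "steady": run_transient(model58, heads_ss, base_ss.state),
    }
    return runs


@pytest.fixture(scope="session")
def season_budgets(season_runs):
    return {k: boundary_fluxes(t) for k, t in season_runs.items()}


@pytest.fixture(scope="session")
def small_sweep(model58, compressed_heads, compressed_heads_nodam):
    """Desk-scale path-length sweep shared by ensemble and acceptance tests."""
    from hyporheic.ensembles import sweep_path_lengths
    lengths = [5.0, 8.0, 12.0, 16.0, 22.0, 30.0]
    return sweep_path_lengths(model58, compressed_heads,
                              compressed_heads_nodam, lengths,
                              spin_up_hours=2000)


@pytest.fixture(scope="session")
def morris_results(model58, compressed_heads):
    """Morris analyses for the three length bands (desk-scale r)."""
    from hyporheic.ensembles import MORRIS_BANDS, morris_sensitivity
    out = {}
    for band, r in zip(MORRIS_BANDS, (6, 4, 4)):
        out[band] = morris_sensitivity(model58, compressed_heads, band,
                                       r=r, seed=0, spin_up_hours=2000)
    return out


@pytest.fixture(scope="session")
def marched_crossings(model58):
    """Da_DO = 1 crossings of the marched quasi-steady state at the
    three printed gradient extremes."""
    from hyporheic.damkohler import damkohler_profile
    from hyporheic.flow import velocity_from_gradient
    out = {}
    for g in (0.017, 0.0073, 0.0061):
        res = spin_up(model58, g)
        v = float(velocity_from_gradient(g, model58.geometry, model58.water))
        da = damkohler_profile(res.state, v, model58.geometry, model58.network)
        out[g] = da.crossing_m
    return out
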