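# hyporheic

Reactive-transport analysis of how a beaver dam, versus seasonal
hydrologic extremes, reshapes redox zonation and nitrate removal in a
riparian hyporheic zone.

Mountain rivers exchange water with the shallow subsurface along
hyporheic flow paths. Whether such a path is a net source or sink of
reactive nitrogen is set by the competition between advective supply of
dissolved oxygen (DO) and microbial demand for it: where DO persists,
nitrification produces nitrate; where DO is exhausted, denitrification
removes it. A beaver dam steeply raises the upstream stage, multiplying
the hydraulic gradient `i = (h_up − h_dn)/L` far beyond what snowmelt
extremes achieve, pushing the oxic zone deeper into the sediment and
driving more nitrate through the system. This package implements that
full analysis chain for a 1D saturated flow path:

* **synthetic hydrology** — seasonal boundary stage series with snowmelt
  peak, recession, a beaver-dam ramp, and the no-dam counterfactual that
  freezes the pre-dam head difference;
* **Darcy flow** — `q = K i`, `v = q/n`, with `K = k ρ g/μ_w` from
  intrinsic permeability (defaults: k = 2.26×10⁻¹¹ m², n = 0.2);
* **reaction network** — Monod kinetics with inhibition,
  `R = μ_max X_im · C_S/(K_S+C_S) · C_TEA/(K_TEA+C_TEA) · K_I/(K_I+C_I)`,
  for aerobic respiration, nitrification (rate tied to the aerobic rate
  via the free-energy ratio) and denitrification; TST calcite kinetics;
  equilibrium SOM→acetate dissolution and zeroth-order ammonification;
* **transport** — operator-split upwind advection (CFL-sub-stepped,
  0.1 m cells, ≤1 h steps) with a per-cell adaptive Dormand–Prince
  reaction integrator (rtol 10⁻⁸, numba-compiled);
* **Damköhler zonation** — `Da_DO = (i/v)·(R_O2/m_O2)` per cell; the
  Da = 1 crossing marks the aerobic/anaerobic transition;
* **nitrate budgets** — boundary-difference removal per m² of discharge
  cross-section, plus a process-resolved nitrogen ledger that must close
  the global N balance within 0.5 %;
* **ensembles** — path-length sweeps (5–70 m), Monte Carlo over the
  oxygen-consuming rate constants, and a native Morris
  elementary-effects sensitivity analysis.

See `docs/methods.md` for the model assumptions, parameter fixtures and
numerical choices.

## Worked example

Quasi-steady redox zonation of the 58 m study path at the three
hydraulic-gradient extremes, then one full dammed season:

```python
import hyporheic as hp
from hyporheic.ensembles import steady_crossing
from hyporheic.transport import spin_up, run_transient
from hyporheic.budget import boundary_fluxes

model = hp.FlowPathModel(geometry=hp.FlowPathGeometry(58.0))
for g in (0.017, 0.0073, 0.0061):          # dam max, 2018 peak, 2019 peak
    print(f"i = {g}: Da=1 at {steady_crossing(model, g):.2f} m")

heads = hp.generate_season(hp.scenario_2018())
base = spin_up(model, float(heads.gradient[0]))
bud = boundary_fluxes(run_transient(model, heads, base.state))
print(f"cumulative NO3 removed: {bud.cumulative_removed:.3f} mol/m2 "
      f"over {bud.window_days:.0f} d")
```

prints

```
i = 0.017: Da=1 at 4.37 m
i = 0.0073: Da=1 at 1.88 m
i = 0.0061: Da=1 at 1.57 m
cumulative NO3 removed: 0.320 mol/m2 over 207 d
```

The aerobic zone under the dam-maximum gradient reaches 4.37 m into the
sediment — about 2.8× its extent at the strongest snowmelt gradient,
exactly the ratio of the gradients, because at quasi-steady state the
transition distance scales linearly with velocity. The cumulative
removal is the nitrate imported minus exported over the season; on this
path everything imported is denitrified.

A thin CLI wraps the same library:

```bash
hyporheic generate-hydro            # write the synthetic head series
hyporheic damkohler --gradient 0.017
hyporheic simulate --heads heads_2018.csv --label 2018
hyporheic sweep && hyporheic montecarlo && hyporheic morris
```

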