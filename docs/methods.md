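# Methods

`hyporheic` simulates oxygen and reactive-nitrogen cycling along a 1D
saturated hyporheic flow path in a mountain riparian zone, and quantifies
how a beaver dam versus seasonal hydrologic extremes reshapes redox
zonation and nitrate removal.  This note records the model, its
assumptions, the parameter choices that matter, and what the synthetic
study conditions do and do not represent.

## Flow

Flow is 1D, fully saturated and quasi-static.  Boundary stages set a
hydraulic gradient `i = (h_up - h_dn)/L`; Darcy flux `q = K i` with
`K = k ρ g / μ_w` from the intrinsic permeability `k = 2.26e-11 m²`
(giving `K ≈ 2.21e-4 m/s` for water at 20 °C, ρ = 998 kg/m³,
μ_w = 1.0e-3 Pa·s — temperature is a configurable assumption); pore
velocity `v = q/n` with porosity `n = 0.2`.  Velocity responds
instantaneously to the boundary heads (no storage term) and is uniform
along the path (incompressible 1D flow).  Flow reversal is permitted;
the inflow face follows the sign of `v`.  Richards-type variably
saturated physics is deliberately out of scope: every simulated path is
saturated, so saturated Darcy flow is the complete description.

## Reaction network

Aqueous species: O₂, NO₃⁻, NH₄⁺, acetate (all DOC), Ca²⁺, DIC, plus a
non-reactive tracer.  Three microbial reactions follow the Monod form

    R = μ_max · X_im · C_S/(K_S+C_S) · C_TEA/(K_TEA+C_TEA) · K_I/(K_I+C_I)

with immobile biomass fixed at `X_im = 1e-5` mol/m³-bulk, zero yield and
no decay.  Stoichiometries are the canonical acetate/N redox couples
(element- and charge-balance checked at construction):

* aerobic respiration: CH₃COO⁻ + 2 O₂ → 2 HCO₃⁻ + H⁺
* nitrification: NH₄⁺ + 2 O₂ → NO₃⁻ + 2 H⁺ + H₂O
* denitrification: CH₃COO⁻ + 8/5 NO₃⁻ + 3/5 H⁺ → 2 HCO₃⁻ + 4/5 N₂ + 4/5 H₂O,
  inhibited by O₂.

The nitrification maximum rate is tied to the aerobic one through the
reaction free energies, `μ_nit = μ_aer · ΔG_nit/ΔG_aer`, with fixture
energies (−800, −288 kJ/mol) whose ratio 0.36 equals the ratio of the
literature rate ranges used in the uncertainty analyses
(aerobic 1.30e-4–2.01e-3, nitrification 4.68e-5–7.26e-4 in
(mol·m³_bulk)/(L·mol_bio·s)).  This guarantees aerobic respiration
preferentially consumes O₂ for any sampled rate.

DOC is supplied solely by equilibrium dissolution of a solid organic
matter (SOM) pool, which pins acetate at 1e-4 M while SOM remains;
ammonification is zeroth-order dissolution of an N-bearing SOM phase
(4e-10 mol/m³-bulk/s, 1 N per mole), sized so ammonium rebuilds over
tens of days in the anoxic zone without ever exhausting the pool within
a season.  Calcite follows the TST law
`R = −A_m (k_n + k_H a_H + k_HCO3 a_HCO3)(1 − Q/K_eq)`; we adopt
"positive = precipitation", so undersaturation (Q < K_eq) yields a
negative (dissolution) rate, suppressed once the mineral is exhausted.
Activity coefficients are 1; `a_H` comes from the boundary pH and
`a_HCO3`/`CO₃²⁻` from carbonate speciation of DIC at 25 °C constants.
pH is held at the boundary value throughout — proton transport and full
aqueous speciation are not modeled.  The headline quantities (DO and N
profiles, Damköhler numbers, nitrate budgets) do not depend on pH
dynamics; calcite is carried for completeness of the water-rock system
and a small reactive surface area (0.1 m²/m³) keeps its feedback on
Ca/DIC gentle.

### Parameter fixtures and the tuned base rate

Half-saturation constants are field-typical fixtures: K_DOC = 1e-3 M
(both heterotrophic reactions), K_O2 = 1e-5 M (both O₂ reactions),
K_NH4 = 1e-6 M, K_NO3 = 1e-5 M.  The O₂ inhibition constant of
denitrification is K_I = 1e-6 M: micromolar-scale inhibition keeps
denitrification effectively silent in oxic water, which is what lets
short, entirely-aerobic flow paths act as net nitrate exporters; a
10-fold weaker inhibition would turn them into net sinks, contradicting
the behaviour the model is meant to represent.

The base-case aerobic maximum rate, μ_aer = 3.113e-4 (μ_nit tied,
μ_den = 5e-4), was calibrated once — by solving the quasi-steady
travel-time profile — so that the Da_DO = 1 transition of the 58 m path
sits at 4.37 m under the dam-maximum gradient (0.017 m/m) — the same
kind of calibration a field application would perform against observed
DO profiles.  It lies comfortably inside the literature range above and
is frozen; all other results (the 1.9 m and 1.6 m transitions at the
seasonal extremes, sweep thresholds, removal ordering) follow from it
without further adjustment.

## Transport numerics

Operator-split marching with steps capped at 1 h: (1) explicit
first-order upwind advection with the Dirichlet river composition at the
inflow face, sub-stepped to CFL ≤ 1 on the 0.1 m grid; (2) a per-cell
reaction update with an adaptive embedded Dormand–Prince 5(4) integrator
at rtol 1e-8 (atol 1e-16), compiled with numba so each cell chooses its
own substeps — only the cells near the oxic/anoxic front are fast; a
pure-NumPy implementation of the same scheme is kept and tested for
equivalence; (3) the equilibrium SOM/acetate restore.  Concentrations
are clipped to zero only below 1e-30; a negative overshoot beyond 1e-9
aborts with a diagnostic.  No explicit dispersion term is included; the
upwind scheme's numerical diffusion (≈ v·Δx/2) is the only mixing and is
the discrete analogue of the diffusion inherent in any finite-volume
reference solution.  Grid refinement 0.1 → 0.05 m moves the aerobic
extent by under 5 %.

Cumulative reaction extents (one accumulator per reaction per cell) are
integrated inside the same RK update, so the process-resolved nitrogen
ledger closes against the boundary fluxes to well within 0.5 % without
any separate bookkeeping quadrature.

Spin-up runs up to 7000 h under constant forcing, terminating early when
the maximum relative per-step change of the aqueous field drops below
1e-10 (solids are excluded from the metric — calcite growth and N-SOM
depletion are secular by construction).  Initial conditions are
immaterial after spin-up; a test verifies the steady state is reached
from both boundary-filled and empty domains.

A continuum quasi-steady solver complements the march: at steady state
under uniform velocity the chemistry of a parcel depends only on its
travel time τ = x/v, so one ODE integration (solids frozen, acetate
pinned) yields the profile at any velocity.  It is used as the fast
engine of the Monte Carlo zonation and as an independent cross-check of
the marched steady state (the two locate the Da_DO = 1 crossing within
a few tenths of a percent on the 58 m path).  An exact corollary, which
the tests assert, is that quasi-steady aerobic extents scale linearly
with the hydraulic gradient regardless of the rate parameters.

## Damköhler zonation and classification

`Da_DO,i = (i/v) · (R_O2,i / m_O2,i)` per cell, with `R_O2` the summed
O₂ consumption of aerobic respiration and nitrification and
`m_O2 = Δx·1·1·n·1000·[O₂]` the cell inventory.  Written as the ratio of
the transport timescale `τ = i/v` to the reaction timescale
`V_O2 = m_O2/R_O2`, the number is dimensionless; defining `V_O2` as the
inverse ratio would give time² and is rejected on dimensional grounds.
The Da = 1 crossing is located by linear interpolation between
bracketing cells, decoupling the metric from Δx; a path whose Da stays
below 1 throughout is flagged "entirely aerobic" (string flag, never an
in-band number).  Flow paths are classified from cumulative boundary
budgets: net-nitrifying (export > import), net-denitrifying
(export ≤ 1e-3 × import), else partial exporter.

## Nitrate budgets

Removal follows the boundary-difference definition — NO₃⁻ flux in at
the inflow face minus flux out at the outflow face, per m² of
cross-sectional discharge area — integrated trapezoidally on the hourly
step cadence.  This definition conflates denitrification with storage
change and internal nitrification, so a process-resolved nitrogen ledger
(N₂ produced, nitrified N, N mineralized from N-SOM, storage change) is
emitted alongside and must close the global N balance within 0.5 %.

On a path that removes all incoming nitrate the boundary-difference
series is gradient-synchronous by construction (outflux ≈ 0, influx
∝ q).  The lag of removal behind the hydraulic forcing — water must
first cross the aerobic zone before its nitrate load reaches the
denitrifying region — therefore lives in the process-resolved series,
and the lag diagnostic cross-correlates the gradient with the
domain-integrated denitrification rate.  With the base
parameterization the lag is of order days (the travel time to the
denitrification front a few metres in), comfortably positive and well
inside twice the full-path travel time at the dam gradient.

## Synthetic study seasons

The generator emulates the two observed seasons as gradient targets:

* 2018 (207 d, Apr 7–Oct 31): day-one gradient 0.0066, snowmelt peak
  0.0073 at day 48, exponential recession (τ = 20 d) to baseflow
  0.005643 — chosen so the pre-dam mean is 0.0065, i.e. the dam maximum
  of 0.017 is a 161.5 % increase; dam ramp Jul 26 → Oct 4, destroyed
  Oct 5 with instant reversion.
* 2019 (168 d, Apr 21–Oct 6): day-one 0.0052, July peak 0.0061,
  recession τ = 25 d to 0.0046 (peak ≈ 15 % above the yearly mean).

The steady-state reference gradient is the mean of the two day-one
means.  Downstream stages carry the seasonal hydrograph shape scaled to
0.3 m; only the head *difference* matters to the physics.  The
counterfactual no-dam series freezes the head difference at its last
pre-construction value so the gradient is constant across the dam
window, mirroring downstream fluctuations exactly.

The path-length sampler draws from a log-normal (median ≈ 33 m,
σ_ln = 0.66) truncated to 5–70 m, a right-skewed stand-in for a
meandering-floodplain path-length distribution.  In the sweep, one set
of stage records forces every length, so a shorter path sees a
proportionally steeper gradient — this, not any per-length retuning, is
what makes short paths flip to entirely-aerobic nitrate exporters when
the dam raises the head difference.

What the synthetic seasons do *not* represent: actual transducer
records (no diel noise, ice effects, barometric artifacts, or hillslope
inflow), the measured path-length histogram, or the field porewater
chemistry series.  Absolute budget magnitudes therefore carry the
fixture boundary concentrations, and only their ratios, orderings and
scalings are meaningful comparisons to field-calibrated results.

## Ensembles

* **Sweep**: lengths 5–70 m at 0.5 m (subsets allowed); per length, spin
  up at the initial gradient, run the dam and no-dam seasons, classify,
  and evaluate quasi-steady aerobic extents at both hydrologic extremes.
  Threshold lengths (largest entirely-aerobic, largest still-exporting)
  are interpolated on the length grid.
* **Monte Carlo**: μ_aer log-uniform over the literature range
  (uniform available), μ_nit re-tied per draw, quasi-steady Da crossing
  at three reference gradients per draw; draw failures are recorded, not
  fatal.  Desk-scale default 200 draws (the analysis is routinely run at
  thousands; the crossing statistics stabilize far earlier).
* **Morris**: native one-at-a-time elementary-effects design (p = 4
  levels, Δ = p/(2(p−1)), r trajectories of k+1 runs), factors
  μ_max-DEN (log), a joint scaling of the O₂-consumption rates (log),
  and path length (linear) within each of the three bands 5–26, 27–48,
  49–70 m.  The response is the cumulative nitrate removed over the
  forcing window.  The design is verified against closed-form elementary
  effects of analytic functions.  Desk-scale runs use a 60 d compressed
  season with the same gradient extremes (dam in the final third) and
  r = 6 for the shortest band, r = 4 elsewhere — the short band mixes
  regime changes from two factors and needs the extra trajectories for a
  stable ranking; the long bands are unambiguous.

## Reproducibility and problem sizes

All stochastic stages take explicit seeds and are bit-reproducible;
deterministic artifacts regenerate identically from a config hash.
Default problem sizes used by the test suite and the acceptance script:
the full 58 m/580-cell path for season runs and zonation; 6–11 length
sweeps; 24–50 Monte Carlo draws; Morris r = 4–6.  These sizes are the
package's desk-scale defaults — every analysis exposes the full-scale
settings through its arguments and the run configuration.

## Known limitations

* pH and full carbonate/ammonia speciation are static; NH₄⁺ is a lumped
  ammonium/ammonia pool fed directly to the nitrification Monod term.
* No microbial growth, decay, or community dynamics; no Fe/S redox.
* No explicit dispersion; mixing is the upwind scheme's numerical
  diffusion, quantified by the grid-refinement test.
* Single 1D path; no 2D meander geometry, hillslope inflow, or
  reach-scale routing of the river nitrate load.
* The boundary composition is fixed in time; real seasonal chemistry
  variation would modulate absolute fluxes.
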