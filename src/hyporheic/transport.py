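"""Coupled 1D advection-reaction marching on the 0.1 m grid.

Operator-split update per (<= 1 h) step: explicit first-order upwind
advection with a Dirichlet inflow concentration at the face selected by
the sign of v, sub-stepped so |v| dt/dx <= 1; then a per-cell reaction
update with an adaptive embedded Runge-Kutta (Dormand-Prince 5(4))
integrator at relative tolerance 1e-8; then the equilibrium SOM/acetate
restore.  No explicit dispersion term is included -- the upwind scheme's
numerical diffusion is the only mixing, as documented in the methods
note.

State layout: aqueous concentrations (mol/L) for the seven tracked
species, solid amounts (mol/m^3 bulk) for calcite and N-SOM, and four
cumulative reaction-extent accumulators (mol/L of substrate turned over,
or of NH4+ released for the N-SOM row) that make budget closure exact
with respect to the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .flow import FlowPathGeometry, WaterProperties, velocity_from_gradient, velocity_series
from .hydrology import BoundaryChemistry, HeadSeries
from .reactions import NetworkParameters, carbonate_fractions, default_network

__all__ = [
    "SPECIES",
    "EXTENTS",
    "FlowPathModel",
    "SimState",
    "SimTrajectory",
    "SpinUpResult",
    "new_state",
    "step",
    "spin_up",
    "run_transient",
    "steady_profile",
]

SPECIES = ("o2", "no3", "nh4", "acetate", "ca", "dic", "tracer")
SOLIDS = ("calcite", "nsom", "som")
EXTENTS = ("aerobic", "nitrification", "denitrification", "nsom")

_IDX = {s: i for i, s in enumerate(SPECIES)}


class TransportError(RuntimeError):
    """Raised when the march diverges (NaN or negative overshoot)."""


@dataclass
class FlowPathModel:
    """Geometry + reaction network + boundary chemistry for one 1D path."""

    geometry: FlowPathGeometry
    network: NetworkParameters = field(default_factory=default_network)
    chemistry: BoundaryChemistry = field(default_factory=BoundaryChemistry)
    water: WaterProperties = field(default_factory=WaterProperties)
    max_dt_h: float = 1.0
    rtol: float = 1.0e-8
    atol: float = 1.0e-16
    inert: bool = False    # skip reactions entirely (conservative transport)

    def __post_init__(self) -> None:
        if self.max_dt_h <= 0 or self.max_dt_h > 1.0 + 1e-12:
            raise ValueError("max timestep must be in (0, 1] h")

    def boundary_vector(self) -> np.ndarray:
        c = self.chemistry
        return np.array([c.o2, c.no3, c.nh4, c.acetate, c.ca, c.dic, c.tracer])


@dataclass
class SimState:
    """Full per-cell state at one instant."""

    t_h: float
    conc: np.ndarray       # (7, N) mol/L
    solids: np.ndarray     # (3, N) mol/m^3 bulk: calcite, nsom, som
    extents: np.ndarray    # (4, N) cumulative mol/L turned over

    def copy(self) -> "SimState":
        return SimState(self.t_h, self.conc.copy(), self.solids.copy(),
                        self.extents.copy())

    def species(self, name: str) -> np.ndarray:
        return self.conc[_IDX[name]]


def new_state(model: FlowPathModel, fill: str = "boundary") -> SimState:
    """Initial condition: domain filled with boundary chemistry (or zeros)."""
    n = model.geometry.n_cells
    if fill == "boundary":
        conc = np.repeat(model.boundary_vector()[:, None], n, axis=1)
    elif fill == "zero":
        conc = np.zeros((len(SPECIES), n))
    else:
        raise ValueError("fill must be 'boundary' or 'zero'")
    s = model.network.solids
    solids = np.vstack([
        np.full(n, s.calcite_amount),
        np.full(n, s.nsom_amount),
        np.full(n, s.som_amount),
    ])
    return SimState(0.0, conc, solids, np.zeros((len(EXTENTS), n)))


# ---------------------------------------------------------------------------
# Reaction right-hand side (vectorized over cells)
# ---------------------------------------------------------------------------

class _ReactionRHS:
    """Precompiled derivative of the 13-row reaction state."""

    N_ROWS = len(SPECIES) + 2 + len(EXTENTS)   # species + calcite,nsom + extents

    def __init__(self, model: FlowPathModel):
        net = model.network
        self.w = model.geometry.porosity * 1000.0   # L water / m^3 bulk
        self.rxns = []
        for k, rxn in enumerate((net.aerobic, net.nitrification,
                                 net.denitrification)):
            col = np.zeros(len(SPECIES))
            for sp, coef in rxn.stoichiometry.items():
                if sp == "hco3":
                    col[_IDX["dic"]] += coef
                elif sp in _IDX:
                    col[_IDX[sp]] += coef
            inh = _IDX[rxn.inhibitor] if rxn.inhibitor else None
            self.rxns.append((rxn.mu_max * rxn.X_im, _IDX[rxn.substrate],
                              rxn.K_S, _IDX[rxn.tea], rxn.K_TEA, inh,
                              rxn.K_I, col, k))
        self.kin = net.calcite
        ph = model.chemistry.ph
        self.a_h = 10.0 ** -ph
        self.f_hco3, self.f_co3 = carbonate_fractions(ph)
        self.nsom_src = net.solids.nsom_rate * net.solids.nsom_n_stoich / self.w
        self.nsom_rate = net.solids.nsom_rate
        self.i_ca, self.i_dic = _IDX["ca"], _IDX["dic"]
        self.n_species = len(SPECIES)

    def __call__(self, y: np.ndarray) -> np.ndarray:
        ns = self.n_species
        conc = np.maximum(y[:ns], 0.0)
        calcite = y[ns]
        nsom = y[ns + 1]
        dy = np.zeros_like(y)

        for muX, i_s, K_S, i_t, K_T, i_i, K_I, col, k in self.rxns:
            rate = (muX * conc[i_s] / (K_S + conc[i_s])
                    * conc[i_t] / (K_T + conc[i_t]))
            if i_i is not None:
                rate = rate * K_I / (K_I + conc[i_i])
            dy[:ns] += col[:, None] * rate
            dy[ns + 2 + k] = rate

        # calcite TST (positive = precipitation); dissolution halts at 0
        dic = conc[self.i_dic]
        a_hco3 = self.f_hco3 * dic
        Q = conc[self.i_ca] * self.f_co3 * dic
        k_sum = (self.kin.k_neutral + self.kin.k_proton * self.a_h
                 + self.kin.k_bicarbonate * a_hco3)
        r_cal = -self.kin.surface_area * k_sum * (1.0 - Q / self.kin.k_eq)
        r_cal = np.where((calcite <= 0) & (r_cal < 0), 0.0, r_cal)
        dy[self.i_ca] -= r_cal / self.w
        dy[self.i_dic] -= r_cal / self.w
        dy[ns] = r_cal

        # N-SOM ammonification: zeroth-order until the pool is exhausted
        active = nsom > 0
        dy[_IDX["nh4"]] += np.where(active, self.nsom_src, 0.0)
        dy[ns + 1] = np.where(active, -self.nsom_rate, 0.0)
        dy[ns + 2 + 3] = np.where(active, self.nsom_src, 0.0)
        return dy


def _rhs_bundle(rhs: "_ReactionRHS") -> tuple:
    """Flatten the compiled RHS into plain arrays for the numba kernel."""
    n_rows = _ReactionRHS.N_ROWS
    cols = np.zeros((3, n_rows))
    rxn_par = np.zeros((3, 6))       # muX, K_S, K_TEA, K_I, (unused), (unused)
    rxn_idx = np.zeros((3, 3), dtype=np.int64)   # sub, tea, inh (-1 none)
    ns = len(SPECIES)
    for (muX, i_s, K_S, i_t, K_T, i_i, K_I, col, k) in rhs.rxns:
        cols[k, :ns] = col
        cols[k, ns + 2 + k] = 1.0    # extent accumulator
        rxn_par[k, 0] = muX
        rxn_par[k, 1] = K_S
        rxn_par[k, 2] = K_T
        rxn_par[k, 3] = K_I if K_I is not None else 0.0
        rxn_idx[k] = (i_s, i_t, i_i if i_i is not None else -1)
    kin = rhs.kin
    misc = np.array([
        kin.surface_area, kin.k_neutral, kin.k_proton, kin.k_bicarbonate,
        kin.k_eq, rhs.a_h, rhs.f_hco3, rhs.f_co3, rhs.w,
        rhs.nsom_src, rhs.nsom_rate,
    ])
    return cols, rxn_par, rxn_idx, misc


try:
    from numba import njit as _njit
    _NUMBA = True
except Exception:     # pragma: no cover - numba is a hard dependency in practice
    _NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=True)
def _cell_rhs(y, dy, cols, rxn_par, rxn_idx, misc):     # pragma: no cover
    ns = 7
    for i in range(y.shape[0]):
        dy[i] = 0.0
    for k in range(3):
        c_s = max(y[rxn_idx[k, 0]], 0.0)
        c_t = max(y[rxn_idx[k, 1]], 0.0)
        rate = (rxn_par[k, 0] * c_s / (rxn_par[k, 1] + c_s)
                * c_t / (rxn_par[k, 2] + c_t))
        if rxn_idx[k, 2] >= 0:
            c_i = max(y[rxn_idx[k, 2]], 0.0)
            rate *= rxn_par[k, 3] / (rxn_par[k, 3] + c_i)
        for i in range(y.shape[0]):
            dy[i] += cols[k, i] * rate
    # calcite (positive = precipitation)
    dic = max(y[5], 0.0)
    ca = max(y[4], 0.0)
    a_hco3 = misc[6] * dic
    Q = ca * misc[7] * dic
    k_sum = misc[1] + misc[2] * misc[5] + misc[3] * a_hco3
    r_cal = -misc[0] * k_sum * (1.0 - Q / misc[4])
    if y[ns] <= 0.0 and r_cal < 0.0:
        r_cal = 0.0
    dy[4] -= r_cal / misc[8]
    dy[5] -= r_cal / misc[8]
    dy[ns] = r_cal
    # N-SOM ammonification
    if y[ns + 1] > 0.0:
        dy[2] += misc[9]
        dy[ns + 1] = -misc[10]
        dy[ns + 2 + 3] = misc[9]
    else:
        dy[ns + 1] = 0.0
        dy[ns + 2 + 3] = 0.0


@_njit(cache=True)
def _integrate_cells(Y, dt_s, rtol, atol, cols, rxn_par, rxn_idx,
                     misc):     # pragma: no cover
    """Per-cell adaptive DOPRI5(4) over one transport step."""
    a = np.zeros((6, 6))
    a[0, 0] = 1 / 5
    a[1, 0] = 3 / 40; a[1, 1] = 9 / 40
    a[2, 0] = 44 / 45; a[2, 1] = -56 / 15; a[2, 2] = 32 / 9
    a[3, 0] = 19372 / 6561; a[3, 1] = -25360 / 2187
    a[3, 2] = 64448 / 6561; a[3, 3] = -212 / 729
    a[4, 0] = 9017 / 3168; a[4, 1] = -355 / 33; a[4, 2] = 46732 / 5247
    a[4, 3] = 49 / 176; a[4, 4] = -5103 / 18656
    a[5, 0] = 35 / 384; a[5, 1] = 0.0; a[5, 2] = 500 / 1113
    a[5, 3] = 125 / 192; a[5, 4] = -2187 / 6784; a[5, 5] = 11 / 84
    e = np.array([35 / 384 - 5179 / 57600, 0.0, 500 / 1113 - 7571 / 16695,
                  125 / 192 - 393 / 640, -2187 / 6784 + 92097 / 339200,
                  11 / 84 - 187 / 2100, -1 / 40])
    n_rows, n_cells = Y.shape
    k = np.zeros((7, n_rows))
    y = np.zeros(n_rows)
    yi = np.zeros(n_rows)
    ok = True
    for j in range(n_cells):
        for i in range(n_rows):
            y[i] = Y[i, j]
        t = 0.0
        h = dt_s
        _cell_rhs(y, k[0], cols, rxn_par, rxn_idx, misc)
        while t < dt_s * (1.0 - 1e-14):
            if h > dt_s - t:
                h = dt_s - t
            for s in range(6):
                for i in range(n_rows):
                    acc = 0.0
                    for q in range(s + 1):
                        acc += a[s, q] * k[q, i]
                    yi[i] = y[i] + h * acc
                _cell_rhs(yi, k[s + 1], cols, rxn_par, rxn_idx, misc)
            enorm = 0.0
            for i in range(n_rows):
                err = 0.0
                for q in range(7):
                    err += e[q] * k[q, i]
                err *= h
                sc = atol + rtol * max(abs(y[i]), abs(yi[i]))
                r = abs(err) / sc
                if r > enorm:
                    enorm = r
            if enorm <= 1.0:
                t += h
                for i in range(n_rows):
                    y[i] = yi[i]
                    k[0, i] = k[6, i]
                if not np.isfinite(y[0]):
                    ok = False
                    t = dt_s
            fac = 5.0 if enorm == 0.0 else 0.9 * enorm ** -0.2
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
            h *= fac
        for i in range(n_rows):
            Y[i, j] = y[i]
    return ok


# Dormand-Prince 5(4) tableau
_DP_A = (
    (1 / 5,),
    (3 / 40, 9 / 40),
    (44 / 45, -56 / 15, 32 / 9),
    (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729),
    (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656),
    (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84),
)
_DP_E = np.array([35 / 384 - 5179 / 57600, 0.0, 500 / 1113 - 7571 / 16695,
                  125 / 192 - 393 / 640, -2187 / 6784 + 92097 / 339200,
                  11 / 84 - 187 / 2100, -1 / 40])


def _integrate_reactions(rhs: _ReactionRHS, y: np.ndarray, dt_s: float,
                         rtol: float, atol: float) -> np.ndarray:
    """Adaptive vectorized DOPRI5(4) over one transport step."""
    t, h = 0.0, dt_s
    k1 = rhs(y)
    while t < dt_s * (1 - 1e-14):
        h = min(h, dt_s - t)
        ks = [k1]
        for ai in _DP_A:
            yi = y + h * sum(a * k for a, k in zip(ai, ks))
            ks.append(rhs(yi))
        y5 = yi                          # last stage uses the 5th-order weights
        err = h * sum(e * k for e, k in zip(_DP_E, ks))
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y5))
        enorm = float(np.max(np.abs(err) / scale))
        if enorm <= 1.0:
            t += h
            y, k1 = y5, ks[-1]           # FSAL
            if not np.all(np.isfinite(y)):
                raise TransportError("non-finite state in reaction update")
        fac = 0.9 * (enorm ** -0.2) if enorm > 0 else 5.0
        h *= min(5.0, max(0.2, fac))
    return y


# ---------------------------------------------------------------------------
# Advection and the operator-split step
# ---------------------------------------------------------------------------

def _advect(conc: np.ndarray, cb: np.ndarray, v: float, dt_s: float,
            dx: float, porosity: float,
            flux_accum: np.ndarray | None = None) -> np.ndarray:
    """Explicit first-order upwind advection, CFL-sub-stepped.

    When ``flux_accum`` (shape (2, n_species)) is given, the exact
    discrete boundary-crossing masses (mol per m^2 cross-section; row 0
    inflow, row 1 outflow) are accumulated into it, so conservation
    holds to machine precision against the stored fields.
    """
    if v == 0.0:
        return conc
    cfl_total = abs(v) * dt_s / dx
    n_sub = max(1, int(np.ceil(cfl_total - 1e-12)))
    cfl = cfl_total / n_sub
    col_water_L = dx * porosity * 1000.0      # L of pore water per m^2
    for _ in range(n_sub):
        if v > 0:
            upstream = np.concatenate([cb[:, None], conc[:, :-1]], axis=1)
            c_exit = conc[:, -1]
        else:
            upstream = np.concatenate([conc[:, 1:], cb[:, None]], axis=1)
            c_exit = conc[:, 0]
        if flux_accum is not None:
            flux_accum[0] += cfl * col_water_L * cb
            flux_accum[1] += cfl * col_water_L * c_exit
        conc = conc - cfl * (conc - upstream)
    return conc


def step(model: FlowPathModel, state: SimState, v: float,
         dt_h: float, flux_accum: np.ndarray | None = None) -> SimState:
    """One operator-split transport step of dt_h hours at pore velocity v."""
    if dt_h > model.max_dt_h + 1e-12:
        raise ValueError("dt exceeds the model's maximum timestep")
    dt_s = dt_h * 3600.0
    cb = model.boundary_vector()
    conc = _advect(state.conc, cb, v, dt_s, model.geometry.dx_m,
                   model.geometry.porosity, flux_accum)

    solids = state.solids
    extents = state.extents
    if not model.inert:
        rhs = _rhs_for(model)
        y = np.vstack([conc, solids[:2], extents])
        if _NUMBA:
            bundle = getattr(model, "_bundle", None)
            if bundle is None or bundle[0] is not rhs:
                bundle = (rhs, _rhs_bundle(rhs))
                model._bundle = bundle
            ok = _integrate_cells(y, dt_s, model.rtol, model.atol,
                                  *bundle[1])
            if not ok:
                raise TransportError("non-finite state in reaction update")
        else:
            y = _integrate_reactions(rhs, y, dt_s, model.rtol, model.atol)
        ns = len(SPECIES)
        conc, calcite_nsom, extents = y[:ns], y[ns:ns + 2], y[ns + 2:]
        if float(conc.min()) < -1e-9:
            raise TransportError(
                f"negative overshoot {conc.min():.3e} beyond tolerance")
        conc[(conc < 0) | (np.abs(conc) < 1e-30)] = 0.0

        # equilibrium SOM dissolution restores acetate while SOM lasts
        som = solids[2]
        w = model.geometry.porosity * 1000.0
        deficit = (model.network.solids.acetate_eq - conc[_IDX["acetate"]]) * w
        transfer = np.where(som > 0, np.minimum(deficit, som),
                            np.minimum(deficit, 0.0))
        som = som - transfer
        conc[_IDX["acetate"]] += transfer / w
        solids = np.vstack([np.maximum(calcite_nsom, 0.0), som])
    return SimState(state.t_h + dt_h, conc, solids, extents)


def _rhs_for(model: FlowPathModel) -> _ReactionRHS:
    # cache the compiled RHS on the model; rebuild if the network changed
    cached = getattr(model, "_rhs", None)
    if cached is None or cached[0] is not model.network:
        cached = (model.network, _ReactionRHS(model))
        model._rhs = cached
    return cached[1]


# ---------------------------------------------------------------------------
# Spin-up and transient runs
# ---------------------------------------------------------------------------

@dataclass
class SpinUpResult:
    state: SimState
    hours_run: float
    steadiness: float      # max relative per-step change at termination


def spin_up(model: FlowPathModel, gradient: float, hours: float = 7000.0,
            tol: float = 1.0e-10, dt_h: float = 1.0,
            initial: SimState | None = None) -> SpinUpResult:
    """March to steady state under constant boundary heads.

    Runs ``hours`` of model time (or stops earlier once the maximum
    relative per-step change of the aqueous field falls below ``tol``).
    Solids are excluded from the steadiness metric: calcite growth and
    N-SOM depletion are secular by construction.
    """
    v = float(velocity_from_gradient(gradient, model.geometry, model.water))
    state = (initial or new_state(model)).copy()
    state.t_h = 0.0
    steadiness = np.inf
    t = 0.0
    while t < hours - 1e-9:
        dt = min(dt_h, hours - t)
        prev = state.conc
        state = step(model, state, v, dt)
        t += dt
        num = np.max(np.abs(state.conc - prev), axis=1)
        den = np.maximum(np.max(np.abs(state.conc), axis=1), 1e-300)
        steadiness = float(np.max(num / den))
        if steadiness < tol:
            break
        if not np.all(np.isfinite(state.conc)):
            raise TransportError("divergence during spin-up")
    return SpinUpResult(state, t, steadiness)


@dataclass
class SimTrajectory:
    """Recorded transient run: snapshots plus boundary flux series."""

    model: FlowPathModel
    times_h: np.ndarray          # step-cadence times (from the head series)
    velocity: np.ndarray         # pore velocity at each time (m/s)
    gradient: np.ndarray
    c_in: np.ndarray             # boundary concentrations (7,)
    c_out: np.ndarray            # outflow-face concentrations (n_t, 7)
    extent_sums: np.ndarray      # (n_t, 4) domain-summed reaction extents
    cum_influx: np.ndarray       # (7,) exact discrete boundary influx, mol/m^2
    cum_outflux: np.ndarray      # (7,) exact discrete boundary outflux, mol/m^2
    snap_times_h: np.ndarray
    snapshots: np.ndarray        # (n_snap, 7, n_cells)
    state0: SimState
    state1: SimState
    config_hash: str | None = None
    seed: int | None = None

    @property
    def window_days(self) -> float:
        return float(self.times_h[-1] - self.times_h[0]) / 24.0


def run_transient(model: FlowPathModel, heads: HeadSeries,
                  from_state: SimState, snapshot_every_h: float = 24.0,
                  config_hash: str | None = None,
                  seed: int | None = None) -> SimTrajectory:
    """Drive the path with a head series, recording fluxes and snapshots.

    Velocity is quasi-static: the value at the left sample of each
    interval is used across it.  Boundary-adjacent concentrations are
    recorded at every head sample; full fields at the snapshot cadence
    (daily by default).
    """
    vel = velocity_series(heads, model.geometry, model.water)
    state = from_state.copy()
    state.t_h = float(heads.times_h[0])
    cb = model.boundary_vector()

    n_t = heads.times_h.size
    c_out = np.empty((n_t, len(SPECIES)))
    ext_sums = np.empty((n_t, len(EXTENTS)))
    ext_sums[0] = state.extents.sum(axis=1)
    flux_accum = np.zeros((2, len(SPECIES)))
    snaps, snap_times = [], []

    def outflow_slice(v: float) -> int:
        return -1 if v >= 0 else 0

    c_out[0] = state.conc[:, outflow_slice(vel.pore_velocity[0])]
    state0 = state.copy()
    snaps.append(state.conc.copy())
    snap_times.append(state.t_h)
    next_snap = state.t_h + snapshot_every_h

    for j in range(n_t - 1):
        dt = float(heads.times_h[j + 1] - heads.times_h[j])
        v = float(vel.pore_velocity[j])
        state = step(model, state, v, dt, flux_accum)
        c_out[j + 1] = state.conc[:, outflow_slice(v)]
        ext_sums[j + 1] = state.extents.sum(axis=1)
        if state.t_h >= next_snap - 1e-9:
            snaps.append(state.conc.copy())
            snap_times.append(state.t_h)
            next_snap += snapshot_every_h
    if snap_times[-1] < state.t_h - 1e-9:
        snaps.append(state.conc.copy())
        snap_times.append(state.t_h)

    return SimTrajectory(
        model=model, times_h=heads.times_h.copy(),
        velocity=vel.pore_velocity.copy(), gradient=vel.gradient.copy(),
        c_in=cb, c_out=c_out, extent_sums=ext_sums,
        cum_influx=flux_accum[0], cum_outflux=flux_accum[1],
        snap_times_h=np.asarray(snap_times), snapshots=np.asarray(snaps),
        state0=state0, state1=state, config_hash=config_hash, seed=seed)


# ---------------------------------------------------------------------------
# Continuum quasi-steady profile (travel-time coordinate)
# ---------------------------------------------------------------------------

def steady_profile(model: FlowPathModel, gradient: float) -> np.ndarray:
    """Steady concentrations (7, n_cells) from the travel-time ODE.

    At steady state under uniform velocity, each parcel's chemistry is a
    function of its travel time tau = x/v only, so the profile solves
    dC/dtau = r(C) from the boundary composition, with solids frozen at
    their configured amounts and acetate pinned at the SOM equilibrium
    value while SOM is present.  This is the continuum counterpart of
    the marched (upwind-discretized) steady state and serves as its
    fast, independent cross-check.
    """
    v = float(velocity_from_gradient(gradient, model.geometry, model.water))
    if v <= 0:
        raise ValueError("steady_profile requires a positive gradient")
    rhs = _ReactionRHS(model)
    ns = len(SPECIES)
    i_ace = _IDX["acetate"]
    solids0 = np.array([model.network.solids.calcite_amount,
                        model.network.solids.nsom_amount])
    pin_acetate = model.network.solids.som_amount > 0
    ace_eq = model.network.solids.acetate_eq

    def f(tau, c):
        y = np.concatenate([c, solids0, np.zeros(len(EXTENTS))])[:, None]
        dy = rhs(y)[:ns, 0]
        if pin_acetate:
            dy[i_ace] = 0.0
        return dy

    c0 = model.boundary_vector().astype(float)
    if pin_acetate:
        c0[i_ace] = ace_eq
    taus = model.geometry.x_centers / v
    sol = solve_ivp(f, (0.0, float(taus[-1])), c0, t_eval=taus,
                    method="RK45", rtol=model.rtol, atol=model.atol)
    if not sol.success:
        raise TransportError(f"steady profile integration failed: {sol.message}")
    return np.maximum(sol.y, 0.0)
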