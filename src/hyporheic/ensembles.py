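"""Path-length sweeps, Monte Carlo zonation, and Morris sensitivity.

Three ensemble analyses around the single-path model:

* a sweep over flow-path lengths (5-70 m, 0.5 m grid by default) under
  dam and no-dam forcing, yielding per-length nitrate budgets, redox
  classifications, and the interpolated threshold lengths (largest
  entirely-aerobic path, largest nitrate-exporting path);
* Monte Carlo over the aerobic-respiration maximum rate (nitrification
  tied through the free-energy ratio), recording the Da_DO = 1 crossing
  at reference hydraulic gradients per draw;
* Morris elementary-effects sensitivity of the cumulative nitrate
  removal to the denitrification rate, the overall DO-consumption rate,
  and the flow-path length, implemented natively (p-level grid, one-at-
  a-time trajectories, step Delta = p/(2(p-1))).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .budget import boundary_fluxes
from .damkohler import classify_path, damkohler_profile
from .hydrology import HeadSeries
from .reactions import MU_AER_RANGE, MU_DEN_RANGE
from .flow import velocity_from_gradient
from .transport import SPECIES, FlowPathModel, run_transient, spin_up, steady_profile

__all__ = [
    "SweepResult",
    "MonteCarloResult",
    "MorrisResult",
    "default_length_grid",
    "sweep_path_lengths",
    "monte_carlo_zonation",
    "morris_ee",
    "morris_sensitivity",
    "MORRIS_BANDS",
]

MORRIS_BANDS = ((5.0, 26.0), (27.0, 48.0), (49.0, 70.0))


def steady_crossing(model: FlowPathModel, gradient: float) -> float:
    """Quasi-steady Da_DO = 1 crossing distance (m) at a fixed gradient."""
    prof = steady_profile(model, gradient)
    v = float(velocity_from_gradient(gradient, model.geometry, model.water))
    da = damkohler_profile({s: prof[i] for i, s in enumerate(SPECIES)},
                           v=v, geom=model.geometry, params=model.network)
    return da.crossing_m


def default_length_grid() -> np.ndarray:
    """The 0.5 m sweep grid, 5.0 to 70.0 m inclusive."""
    return np.round(np.arange(5.0, 70.0 + 0.25, 0.5), 6)


# ---------------------------------------------------------------------------
# Path-length sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-length budgets, classifications and aerobic flags."""

    lengths_m: np.ndarray
    imported_dam: np.ndarray
    exported_dam: np.ndarray
    imported_nodam: np.ndarray
    exported_nodam: np.ndarray
    class_dam: list
    class_nodam: list
    aerobic_extent_dam_m: np.ndarray      # quasi-steady x* at the dam maximum
    aerobic_extent_seasonal_m: np.ndarray  # ... at the seasonal maximum
    entirely_aerobic_dam: np.ndarray
    entirely_aerobic_seasonal: np.ndarray

    def aerobic_cutoff_m(self, scenario: str = "dam") -> float:
        """Largest length that is entirely aerobic, by interpolation.

        Solves x*(L) = L on the length grid, where x* is the quasi-steady
        Da_DO = 1 crossing at the scenario's maximum gradient.
        """
        x = (self.aerobic_extent_dam_m if scenario == "dam"
             else self.aerobic_extent_seasonal_m)
        L = self.lengths_m
        margin = np.where(np.isinf(x), 1.0, x - L)   # >0 while aerobic
        below = np.nonzero(margin <= 0)[0]
        if below.size == 0:
            return float(L[-1])
        j = int(below[0])
        if j == 0:
            return float(L[0])
        m0, m1 = margin[j - 1], margin[j]
        return float(L[j - 1] + m0 / (m0 - m1) * (L[j] - L[j - 1]))

    def export_cutoff_m(self, scenario: str = "dam",
                        eps: float = 1.0e-3) -> float:
        """Largest length still exporting nitrate (export > eps*import)."""
        if scenario == "dam":
            imp, exp = self.imported_dam, self.exported_dam
        else:
            imp, exp = self.imported_nodam, self.exported_nodam
        frac = np.where(imp > 0, exp / imp, 0.0)
        L = self.lengths_m
        below = np.nonzero(frac <= eps)[0]
        if below.size == 0:
            return float(L[-1])
        j = int(below[0])
        if j == 0:
            return float(L[0])
        f0, f1 = frac[j - 1], frac[j]
        return float(L[j - 1] + (f0 - eps) / (f0 - f1) * (L[j] - L[j - 1]))


def sweep_path_lengths(base_model: FlowPathModel,
                       heads_with_dam: HeadSeries,
                       heads_no_dam: HeadSeries,
                       lengths: Sequence[float] | None = None,
                       spin_up_hours: float = 7000.0) -> SweepResult:
    """Run the dam / no-dam pair over a grid of flow-path lengths.

    The same stage records (hence the same boundary head *differences*)
    force every length, so shorter paths see proportionally steeper
    gradients.  Reaction network and boundary chemistry are identical
    across lengths.  Any single-path failure aborts with the offending
    length.
    """
    lengths = default_length_grid() if lengths is None else np.asarray(
        lengths, dtype=float)
    g_dam_max = float(np.max(heads_with_dam.gradient)) * heads_with_dam.separation_m
    g_sea_max = float(np.max(heads_no_dam.gradient)) * heads_no_dam.separation_m
    g0 = float(heads_with_dam.gradient[0]) * heads_with_dam.separation_m

    out = {k: [] for k in ("imp_d", "exp_d", "imp_n", "exp_n",
                           "x_dam", "x_sea")}
    cls_d, cls_n = [], []
    for L in lengths:
        try:
            geom = dataclasses.replace(base_model.geometry, length_m=float(L))
            model = dataclasses.replace(base_model, geometry=geom)
            base = spin_up(model, g0 / L, hours=spin_up_hours)
            budgets = []
            for heads in (heads_with_dam, heads_no_dam):
                traj = run_transient(model, heads, base.state)
                budgets.append(boundary_fluxes(traj))
            bud_d, bud_n = budgets
            out["imp_d"].append(bud_d.cumulative_imported)
            out["exp_d"].append(bud_d.cumulative_exported)
            out["imp_n"].append(bud_n.cumulative_imported)
            out["exp_n"].append(bud_n.cumulative_exported)
            cls_d.append(classify_path(bud_d.cumulative_imported,
                                       bud_d.cumulative_exported))
            cls_n.append(classify_path(bud_n.cumulative_imported,
                                       bud_n.cumulative_exported))
            for key, dh in (("x_dam", g_dam_max), ("x_sea", g_sea_max)):
                out[key].append(
                    steady_crossing(model, dh / L))
        except Exception as exc:
            raise RuntimeError(f"sweep failed at length {L} m") from exc

    x_dam = np.array(out["x_dam"])
    x_sea = np.array(out["x_sea"])
    return SweepResult(
        lengths_m=lengths,
        imported_dam=np.array(out["imp_d"]), exported_dam=np.array(out["exp_d"]),
        imported_nodam=np.array(out["imp_n"]), exported_nodam=np.array(out["exp_n"]),
        class_dam=cls_d, class_nodam=cls_n,
        aerobic_extent_dam_m=x_dam, aerobic_extent_seasonal_m=x_sea,
        entirely_aerobic_dam=np.isinf(x_dam) | (x_dam >= lengths),
        entirely_aerobic_seasonal=np.isinf(x_sea) | (x_sea >= lengths),
    )


# ---------------------------------------------------------------------------
# Monte Carlo redox zonation
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloResult:
    """Per-draw rates and Da = 1 crossing distances (m)."""

    mu_aer: np.ndarray
    mu_nit: np.ndarray
    gradients: tuple
    crossings_m: np.ndarray     # (n_draws, n_gradients); inf = entirely aerobic
    seed: int
    failures: int = 0


def monte_carlo_zonation(model: FlowPathModel, n_draws: int = 200,
                         seed: int = 0,
                         gradients: Sequence[float] = (0.0073, 0.0061, 0.017),
                         mu_range: tuple[float, float] = MU_AER_RANGE,
                         distribution: str = "loguniform") -> MonteCarloResult:
    """Sample the aerobic rate constant and map the redox transition.

    Each draw samples mu_aer (log-uniform over the literature range by
    default), re-ties mu_nit through the free-energy ratio, solves the
    quasi-steady profile, and records the Da_DO = 1 crossing at each
    reference gradient.  Draw failures are recorded as NaN, not fatal.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = mu_range
    if distribution == "loguniform":
        draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_draws))
    elif distribution == "uniform":
        draws = rng.uniform(lo, hi, size=n_draws)
    else:
        raise ValueError("distribution must be 'loguniform' or 'uniform'")

    crossings = np.full((n_draws, len(gradients)), np.nan)
    mu_nit = np.empty(n_draws)
    failures = 0
    for d, mu in enumerate(draws):
        net = model.network.with_rates(mu_aer=float(mu))
        mu_nit[d] = net.nitrification.mu_max
        m = dataclasses.replace(model, network=net)
        try:
            for gidx, g in enumerate(gradients):
                crossings[d, gidx] = steady_crossing(m, float(g))
        except Exception:
            failures += 1
    return MonteCarloResult(draws, mu_nit, tuple(gradients), crossings,
                            seed, failures)


# ---------------------------------------------------------------------------
# Morris elementary effects (native implementation)
# ---------------------------------------------------------------------------

@dataclass
class MorrisResult:
    """Elementary-effect summary per factor."""

    names: tuple
    ee: np.ndarray          # (r, k) elementary effects
    mu_star: np.ndarray     # mean absolute EE
    sigma: np.ndarray       # EE standard deviation
    r: int

    @property
    def n_runs(self) -> int:
        return self.r * (len(self.names) + 1)

    def ranking(self) -> list[str]:
        order = np.argsort(self.mu_star)[::-1]
        return [self.names[i] for i in order]


def _map_unit(u: np.ndarray, factors: Sequence[tuple]) -> dict:
    vals = {}
    for ui, (name, lo, hi, scale) in zip(u, factors):
        if scale == "log":
            vals[name] = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        else:
            vals[name] = float(lo + ui * (hi - lo))
    return vals


def morris_ee(func: Callable[[dict], float], factors: Sequence[tuple],
              r: int = 10, p: int = 4, seed: int = 0) -> MorrisResult:
    """One-at-a-time Morris trajectories on a p-level unit grid.

    ``factors`` is a sequence of (name, lo, hi, scale) with scale in
    {"linear", "log"}; degenerate ranges (lo == hi) are rejected.  Each
    of the ``r`` trajectories perturbs every factor once by
    Delta = p/(2(p-1)) in unit space, in random order from a random
    admissible grid point; EE_i = (f(x + Delta e_i) - f(x)) / Delta.
    """
    if r < 4:
        raise ValueError("r must be >= 4")
    for name, lo, hi, scale in factors:
        if not hi > lo:
            raise ValueError(f"degenerate range for factor {name!r}")
    k = len(factors)
    delta = p / (2.0 * (p - 1))
    rng = np.random.default_rng(seed)
    levels = np.arange(p) / (p - 1)
    base_levels = levels[levels <= 1.0 - delta + 1e-12]

    ee = np.empty((r, k))
    for t in range(r):
        u = rng.choice(base_levels, size=k)
        f0 = func(_map_unit(u, factors))
        order = rng.permutation(k)
        current, f_cur = u.copy(), f0
        for i in order:
            nxt = current.copy()
            nxt[i] += delta
            f_nxt = func(_map_unit(nxt, factors))
            ee[t, i] = (f_nxt - f_cur) / delta
            current, f_cur = nxt, f_nxt
    mu_star = np.mean(np.abs(ee), axis=0)
    sigma = np.std(ee, axis=0, ddof=1)
    return MorrisResult(tuple(f[0] for f in factors), ee, mu_star, sigma, r)


def morris_sensitivity(base_model: FlowPathModel, heads: HeadSeries,
                       length_band: tuple[float, float],
                       r: int = 10, p: int = 4, seed: int = 0,
                       mu_den_range: tuple[float, float] = MU_DEN_RANGE,
                       r_do_range: tuple[float, float] = MU_AER_RANGE,
                       spin_up_hours: float = 7000.0,
                       response: str = "removed") -> MorrisResult:
    """Morris analysis of the nitrate mass balance for one length band.

    Factors: the denitrification maximum rate, the overall DO-consumption
    rate (a joint scaling of mu_aer with mu_nit tied), and the flow-path
    length within ``length_band``.  Rates use log scaling.  The response
    is the cumulative nitrate removed (mol/m^2, ``response="removed"``)
    or the exported fraction of imported nitrate
    (``response="exported_fraction"``) over the forcing window.
    """
    if response not in ("removed", "exported_fraction"):
        raise ValueError("response must be 'removed' or 'exported_fraction'")
    dx = base_model.geometry.dx_m
    dh0 = float(heads.gradient[0]) * heads.separation_m

    def _response(fac: dict) -> float:
        L = round(fac["length"] / dx) * dx
        geom = dataclasses.replace(base_model.geometry, length_m=L)
        net = base_model.network.with_rates(mu_aer=fac["r_do"],
                                            mu_den=fac["mu_den"])
        model = dataclasses.replace(base_model, geometry=geom, network=net)
        base = spin_up(model, dh0 / L, hours=spin_up_hours)
        traj = run_transient(model, heads, base.state)
        bud = boundary_fluxes(traj)
        if response == "exported_fraction":
            return bud.cumulative_exported / max(bud.cumulative_imported, 1e-300)
        return bud.cumulative_removed

    factors = [
        ("mu_den", *mu_den_range, "log"),
        ("r_do", *r_do_range, "log"),
        ("length", *length_band, "linear"),
    ]
    return morris_ee(_response, factors, r=r, p=p, seed=seed)
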