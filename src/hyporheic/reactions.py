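"""Biogeochemical reaction network for the riparian hyporheic zone.

Three microbially mediated redox reactions (aerobic respiration of
acetate, nitrification, denitrification) follow a Monod rate law with
half-saturation terms for substrate and terminal electron acceptor and
an optional inhibition factor:

    R_S = mu_max * X_im * C_S/(K_S+C_S) * C_TEA/(K_TEA+C_TEA) * K_I/(K_I+C_I)

with X_im a fixed immobile biomass (no growth, no decay).  Calcite
follows a transition-state-theory rate law with neutral, proton and
bicarbonate mechanisms and a (1 - Q/K_eq) affinity term (positive =
precipitation).  DOC is supplied entirely as acetate by equilibrium
dissolution of a solid organic matter (SOM) phase; ammonium is released
by zeroth-order kinetic dissolution of an N-bearing SOM phase.

The nitrification maximum rate is tied to the aerobic one through the
free-energy ratio, mu_nit = mu_aer * dG_nit/dG_aer, so oxygen is
partitioned between the two O2-consuming reactions consistently with
their energetics (aerobic respiration wins when |dG_aer| > |dG_nit|).

Units: aqueous concentrations mol/L; solid amounts mol/m^3 bulk; Monod
rates mol/(L s) of substrate turnover; mineral rates mol/(m^3 bulk s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "MonodReaction",
    "CalciteKinetics",
    "SolidPhases",
    "NetworkParameters",
    "monod_rate",
    "tie_nitrification_rate",
    "calcite_rate",
    "nsom_ammonification_rate",
    "acetate_equilibrium",
    "overall_DO_consumption",
    "carbonate_fractions",
    "default_network",
    "MU_AER_RANGE",
    "MU_NIT_RANGE",
    "MU_DEN_RANGE",
    "MU_NIT_TO_AER",
]

# Literature-derived plausible ranges for the oxygen-consuming maximum
# rates, (mol m^3_bulk)/(L mol_bio s); nitrification tied at ratio 0.36.
MU_AER_RANGE = (1.30e-4, 2.01e-3)
MU_NIT_RANGE = (4.68e-5, 7.26e-4)
MU_DEN_RANGE = (3.13e-5, 2.57e-3)
MU_NIT_TO_AER = 0.36

# Base-case maximum rate for aerobic respiration, tuned once so that the
# quasi-steady Da_DO = 1 crossing of the 58 m path sits at 4.37 m under
# the dam-maximum gradient (0.017 m/m); see docs/methods.md.
MU_AER_BASE = 3.113e-4
MU_DEN_BASE = 5.0e-4

X_IM_DEFAULT = 1.0e-5   # mol-biomass / m^3-bulk, fixed in all simulations

# Element/charge bookkeeping for stoichiometry validation.
_COMPOSITION: dict[str, tuple[dict[str, int], int]] = {
    "o2":      ({"O": 2}, 0),
    "no3":     ({"N": 1, "O": 3}, -1),
    "nh4":     ({"N": 1, "H": 4}, +1),
    "acetate": ({"C": 2, "H": 3, "O": 2}, -1),
    "hco3":    ({"C": 1, "H": 1, "O": 3}, -1),
    "ca":      ({"Ca": 1}, +2),
    "h+":      ({"H": 1}, +1),
    "h2o":     ({"H": 2, "O": 1}, 0),
    "n2":      ({"N": 2}, 0),
}


def _check_balance(name: str, stoich: Mapping[str, float]) -> None:
    totals: dict[str, float] = {}
    charge = 0.0
    for sp, coef in stoich.items():
        comp, z = _COMPOSITION[sp]
        charge += coef * z
        for el, cnt in comp.items():
            totals[el] = totals.get(el, 0.0) + coef * cnt
    bad = {el: t for el, t in totals.items() if abs(t) > 1e-9}
    if bad or abs(charge) > 1e-9:
        raise ValueError(
            f"stoichiometry of {name!r} unbalanced: elements {bad}, charge {charge}")


@dataclass(frozen=True)
class MonodReaction:
    """One Monod-kinetics reaction with optional inhibition.

    ``stoichiometry`` maps species to signed mole coefficients per mole
    of substrate turned over (substrate coefficient -1); it must balance
    every element and charge.
    """

    name: str
    mu_max: float
    substrate: str
    K_S: float
    tea: str
    K_TEA: float
    stoichiometry: Mapping[str, float]
    X_im: float = X_IM_DEFAULT
    inhibitor: str | None = None
    K_I: float | None = None

    def __post_init__(self) -> None:
        if min(self.mu_max, self.K_S, self.K_TEA, self.X_im) <= 0:
            raise ValueError(f"{self.name}: rate and K parameters must be > 0")
        if (self.inhibitor is None) != (self.K_I is None):
            raise ValueError(f"{self.name}: inhibitor and K_I go together")
        if self.K_I is not None and self.K_I <= 0:
            raise ValueError(f"{self.name}: K_I must be > 0")
        if self.stoichiometry.get(self.substrate, 0) >= 0:
            raise ValueError(f"{self.name}: substrate must be consumed")
        _check_balance(self.name, self.stoichiometry)

    def with_mu(self, mu_max: float) -> "MonodReaction":
        return dataclasses.replace(self, mu_max=mu_max)


def monod_rate(rxn: MonodReaction, concentrations: Mapping[str, object]):
    """Substrate turnover rate, mol/(L s), Monod dual-limitation form.

    The inhibition factor is 1 when no inhibitor is configured.  Negative
    concentrations are rejected: callers clip first.
    """
    c_s = np.asarray(concentrations[rxn.substrate], dtype=float)
    c_tea = np.asarray(concentrations[rxn.tea], dtype=float)
    if np.any(c_s < 0) or np.any(c_tea < 0):
        raise ValueError("negative concentration passed to monod_rate")
    rate = (rxn.mu_max * rxn.X_im
            * c_s / (rxn.K_S + c_s)
            * c_tea / (rxn.K_TEA + c_tea))
    if rxn.inhibitor is not None:
        c_i = np.asarray(concentrations[rxn.inhibitor], dtype=float)
        if np.any(c_i < 0):
            raise ValueError("negative inhibitor concentration")
        rate = rate * rxn.K_I / (rxn.K_I + c_i)
    return rate


def tie_nitrification_rate(mu_aer: float, dG_aer: float, dG_nit: float) -> float:
    """mu_nit = mu_aer * dG_nit / dG_aer (same sign convention)."""
    if dG_aer == 0:
        raise ValueError("dG_aer must be nonzero")
    if dG_aer * dG_nit < 0:
        raise ValueError("dG values must share a sign convention")
    return mu_aer * dG_nit / dG_aer


# ---------------------------------------------------------------------------
# Calcite TST kinetics
# ---------------------------------------------------------------------------

# 25 degC carbonate equilibria (activity coefficients taken as 1).
K1_CARBONATE = 10.0 ** -6.35
K2_CARBONATE = 10.0 ** -10.33
CALCITE_KSP = 10.0 ** -8.48


def carbonate_fractions(ph: float) -> tuple[float, float]:
    """(HCO3-, CO3--) fractions of DIC at the given pH."""
    h = 10.0 ** -ph
    denom = h * h + h * K1_CARBONATE + K1_CARBONATE * K2_CARBONATE
    f_hco3 = h * K1_CARBONATE / denom
    f_co3 = K1_CARBONATE * K2_CARBONATE / denom
    return f_hco3, f_co3


@dataclass(frozen=True)
class CalciteKinetics:
    """TST calcite rate law; positive rate = precipitation.

    R = -A_m (k_n + k_H a_H + k_HCO3 a_HCO3) (1 - Q/K_eq): undersaturation
    (Q < K_eq) gives a negative rate (dissolution), supersaturation a
    positive one.  Rate constants are 25 degC values per unit surface.
    """

    surface_area: float = 0.1      # m^2 / m^3 bulk
    k_neutral: float = 1.55e-6     # mol / m^2 s
    k_proton: float = 0.5
    k_bicarbonate: float = 3.3e-4
    k_eq: float = CALCITE_KSP

    def __post_init__(self) -> None:
        if min(self.surface_area, self.k_neutral, self.k_proton,
               self.k_bicarbonate) < 0 or self.k_eq <= 0:
            raise ValueError("calcite kinetic parameters must be non-negative")


def calcite_rate(kin: CalciteKinetics, a_h: float, a_hco3, Q,
                 mineral_amount=None):
    """Calcite rate, mol/(m^3 bulk s); positive = precipitation.

    Dissolution is suppressed where the mineral is exhausted.
    """
    a_hco3 = np.asarray(a_hco3, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if a_h <= 0 or np.any(a_hco3 < 0) or np.any(Q < 0):
        raise ValueError("activities must be positive, Q >= 0")
    k_sum = kin.k_neutral + kin.k_proton * a_h + kin.k_bicarbonate * a_hco3
    rate = -kin.surface_area * k_sum * (1.0 - Q / kin.k_eq)
    if mineral_amount is not None:
        rate = np.where((np.asarray(mineral_amount) <= 0) & (rate < 0), 0.0, rate)
    return rate


# ---------------------------------------------------------------------------
# Solid organic matter phases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolidPhases:
    """SOM (equilibrium acetate source) and N-SOM (kinetic NH4+ source).

    Amounts are per m^3 bulk.  SOM buffers acetate at ``acetate_eq``
    until exhausted; N-SOM dissolves at the constant (zeroth-order in
    solutes) rate ``nsom_rate`` releasing ``nsom_n_stoich`` mol NH4+ per
    mol dissolved.  Defaults are ample so neither pool runs out over a
    season; calcite inventory included here for convenience.
    """

    som_amount: float = 100.0
    acetate_eq: float = 1.0e-4
    nsom_amount: float = 50.0
    nsom_rate: float = 4.0e-10     # mol / m^3 bulk s
    nsom_n_stoich: float = 1.0
    calcite_amount: float = 10.0

    def __post_init__(self) -> None:
        if min(self.som_amount, self.nsom_amount, self.calcite_amount) < 0:
            raise ValueError("solid amounts must be >= 0")
        if self.acetate_eq < 0 or self.nsom_rate < 0 or self.nsom_n_stoich < 0:
            raise ValueError("solid-phase parameters must be >= 0")


def nsom_ammonification_rate(solid: SolidPhases, nsom_amount=None):
    """NH4+ source from N-SOM dissolution, mol/(m^3 bulk s).

    Zeroth-order in solutes; zero wherever the N-SOM pool is exhausted.
    """
    amount = solid.nsom_amount if nsom_amount is None else nsom_amount
    amount = np.asarray(amount, dtype=float)
    rate = solid.nsom_rate * solid.nsom_n_stoich
    return np.where(amount > 0, rate, 0.0)


def acetate_equilibrium(solid: SolidPhases, current_acetate,
                        som_amount=None, porosity: float = 0.2):
    """Equilibrium SOM dissolution: restore acetate to its set point.

    Returns ``(new_acetate, new_som)`` for arrays of current acetate
    (mol/L) and SOM amounts (mol/m^3 bulk).  The transferred acetate is
    debited from (or credited to) SOM; once SOM is exhausted acetate is
    free to deplete.  Per-cell bulk-to-water conversion uses
    ``porosity * 1000`` L of water per m^3 bulk.
    """
    ace = np.asarray(current_acetate, dtype=float)
    som = np.asarray(solid.som_amount if som_amount is None else som_amount,
                     dtype=float)
    w = porosity * 1000.0    # L water per m^3 bulk
    deficit = (solid.acetate_eq - ace) * w          # mol/m^3 bulk to transfer
    transfer = np.where(som > 0, np.minimum(deficit, som), np.minimum(deficit, 0.0))
    new_som = som - transfer
    new_ace = ace + transfer / w
    return new_ace, new_som


# ---------------------------------------------------------------------------
# Assembled network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkParameters:
    """The full reaction network for one flow-path model."""

    aerobic: MonodReaction
    nitrification: MonodReaction
    denitrification: MonodReaction
    calcite: CalciteKinetics
    solids: SolidPhases
    dG_aer: float = -800.0    # kJ/mol reaction, fixture values with
    dG_nit: float = -288.0    # dG_nit/dG_aer = 0.36

    def __post_init__(self) -> None:
        tied = tie_nitrification_rate(self.aerobic.mu_max, self.dG_aer, self.dG_nit)
        if abs(tied - self.nitrification.mu_max) > 1e-12 * abs(tied):
            raise ValueError("mu_aer:mu_nit must equal dG_aer:dG_nit")

    def with_rates(self, mu_aer: float | None = None,
                   mu_den: float | None = None) -> "NetworkParameters":
        """Copy with new maximum rates; mu_nit re-tied to mu_aer."""
        aer = self.aerobic if mu_aer is None else self.aerobic.with_mu(mu_aer)
        nit = self.nitrification.with_mu(
            tie_nitrification_rate(aer.mu_max, self.dG_aer, self.dG_nit))
        den = (self.denitrification if mu_den is None
               else self.denitrification.with_mu(mu_den))
        return dataclasses.replace(self, aerobic=aer, nitrification=nit,
                                   denitrification=den)


def overall_DO_consumption(concentrations: Mapping[str, object],
                           params: NetworkParameters,
                           geom=None):
    """O2 consumption rate from aerobic respiration plus nitrification.

    Returns mol O2 /(L s) by default; with ``geom`` given, scales to mol
    O2 /s per grid cell (times the cell pore-water volume in liters).
    """
    r = (-params.aerobic.stoichiometry["o2"]
         * monod_rate(params.aerobic, concentrations)
         - params.nitrification.stoichiometry["o2"]
         * monod_rate(params.nitrification, concentrations))
    if geom is not None:
        r = r * geom.cell_water_volume_L
    return r


def default_network(mu_aer: float = MU_AER_BASE,
                    mu_den: float = MU_DEN_BASE,
                    solids: SolidPhases | None = None,
                    calcite: CalciteKinetics | None = None,
                    dG_aer: float = -800.0,
                    dG_nit: float = -288.0) -> NetworkParameters:
    """Base-case network with canonical acetate/N redox stoichiometries.

    Aerobic respiration  CH3COO- + 2 O2 -> 2 HCO3- + H+
    Nitrification        NH4+ + 2 O2 -> NO3- + 2 H+ + H2O
    Denitrification      CH3COO- + 8/5 NO3- + 3/5 H+ -> 2 HCO3- + 4/5 N2 + 4/5 H2O
    """
    mu_nit = tie_nitrification_rate(mu_aer, dG_aer, dG_nit)
    aerobic = MonodReaction(
        name="aerobic_respiration", mu_max=mu_aer,
        substrate="acetate", K_S=1.0e-3, tea="o2", K_TEA=1.0e-5,
        stoichiometry={"acetate": -1.0, "o2": -2.0, "hco3": 2.0, "h+": 1.0},
    )
    nitrification = MonodReaction(
        name="nitrification", mu_max=mu_nit,
        substrate="nh4", K_S=1.0e-6, tea="o2", K_TEA=1.0e-5,
        stoichiometry={"nh4": -1.0, "o2": -2.0, "no3": 1.0,
                       "h+": 2.0, "h2o": 1.0},
    )
    denitrification = MonodReaction(
        name="denitrification", mu_max=mu_den,
        substrate="acetate", K_S=1.0e-3, tea="no3", K_TEA=1.0e-5,
        inhibitor="o2", K_I=1.0e-6,
        stoichiometry={"acetate": -1.0, "no3": -1.6, "h+": -0.6,
                       "hco3": 2.0, "n2": 0.8, "h2o": 0.8},
    )
    return NetworkParameters(
        aerobic=aerobic, nitrification=nitrification,
        denitrification=denitrification,
        calcite=calcite or CalciteKinetics(),
        solids=solids or SolidPhases(),
        dG_aer=dG_aer, dG_nit=dG_nit,
    )
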