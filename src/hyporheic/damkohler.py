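"""Damköhler redox zonation metrics for dissolved oxygen.

Da_DO at a point i along the path is the ratio of the water transport
timescale tau = i/v to the DO reaction timescale m_O2/R_O2 evaluated
from the local concentrations:

    Da_DO,i = (i / v) * (R_O2,i / m_O2,i)

with R_O2 the summed O2 consumption of aerobic respiration and
nitrification (mol O2/s per cell) and m_O2 the cell O2 inventory (mol).
Da_DO = 1 marks the aerobic-to-anaerobic transition: upstream of it,
advection controls DO; beyond it, microbial demand outpaces supply.
The crossing is located by linear interpolation between bracketing
cells so the metric is decoupled from the grid spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .flow import FlowPathGeometry
from .reactions import NetworkParameters, monod_rate

__all__ = [
    "DamkohlerProfile",
    "PathClassification",
    "moles_O2_in_cell",
    "damkohler_profile",
    "aerobic_extent",
    "classify_path",
]


def moles_O2_in_cell(concentration, geom: FlowPathGeometry):
    """O2 inventory of one cell: dx * 1 * 1 * porosity * 1000 * [O2] (mol)."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    return geom.dx_m * 1.0 * 1.0 * geom.porosity * 1000.0 * c


@dataclass
class DamkohlerProfile:
    """Per-cell Damköhler profile and the Da = 1 crossing."""

    x_m: np.ndarray            # distance of cell centers from the inflow face
    tau_s: np.ndarray          # transport timescale x/v
    R_O2: np.ndarray           # O2 consumption, mol/s per cell
    m_O2: np.ndarray           # O2 inventory, mol per cell
    Da: np.ndarray
    crossing_m: float          # +inf when the whole path stays below Da = 1
    entirely_aerobic: bool

    @property
    def crossing_label(self) -> str:
        return "entirely_aerobic" if self.entirely_aerobic else f"{self.crossing_m:.6g}"


def aerobic_extent(x_m: np.ndarray, Da: np.ndarray) -> tuple[float, bool]:
    """First x where Da >= 1, linearly interpolated; (+inf, True) if none."""
    above = np.nonzero(Da >= 1.0)[0]
    if above.size == 0:
        return math.inf, True
    j = int(above[0])
    if j == 0:
        return float(x_m[0]), False
    x0, x1 = x_m[j - 1], x_m[j]
    d0, d1 = Da[j - 1], Da[j]
    x_star = x0 + (1.0 - d0) / (d1 - d0) * (x1 - x0)
    return float(x_star), False


def damkohler_profile(conc, v: float, geom: FlowPathGeometry,
                      params: NetworkParameters) -> DamkohlerProfile:
    """Evaluate Da_DO at every cell from a concentration field.

    ``conc`` maps species names to per-cell arrays (a SimState's view or
    a plain dict with at least o2, acetate, nh4, no3).  ``v`` is the
    pore velocity (m/s); it must be nonzero, otherwise Da is undefined.
    Distances are measured from the inflow face (downstream face when v
    is negative).
    """
    if v == 0.0:
        raise ValueError("Da undefined at zero velocity")
    if hasattr(conc, "species"):
        conc = {name: conc.species(name)
                for name in ("o2", "no3", "nh4", "acetate")}
    o2 = np.asarray(conc["o2"], dtype=float)
    x = geom.x_centers
    if v < 0:
        x = geom.length_m - x[::-1]      # same centers, measured from the
        conc = {k: np.asarray(a)[::-1] for k, a in conc.items()}  # other face
        o2 = o2[::-1]

    vol_L = geom.cell_water_volume_L
    rate_o2 = (-params.aerobic.stoichiometry["o2"] * monod_rate(params.aerobic, conc)
               - params.nitrification.stoichiometry["o2"]
               * monod_rate(params.nitrification, conc))   # mol/(L s)
    R = rate_o2 * vol_L                                    # mol/s per cell
    m = moles_O2_in_cell(o2, geom)
    tau = x / abs(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        Da = np.where(m > 0, tau * R / m, 0.0)
    x_star, aerobic = aerobic_extent(x, Da)
    return DamkohlerProfile(x, tau, R, m, Da, x_star, aerobic)


@dataclass
class PathClassification:
    """Net redox behaviour of one flow path over an analysis window."""

    label: str                  # net-nitrifying | partial-exporter | net-denitrifying
    imported_mol_m2: float
    exported_mol_m2: float
    degenerate: bool = False


def classify_path(imported: float, exported: float,
                  eps: float = 1.0e-3) -> PathClassification:
    """Classify by cumulative NO3- import vs export.

    net-nitrifying: exported > imported; net-denitrifying: exported <=
    eps * imported; otherwise partial-exporter.  A path with no import
    and no export is flagged degenerate (classified net-denitrifying).
    """
    if imported == 0.0 and exported == 0.0:
        return PathClassification("net-denitrifying", 0.0, 0.0, degenerate=True)
    if exported > imported:
        label = "net-nitrifying"
    elif exported <= eps * imported:
        label = "net-denitrifying"
    else:
        label = "partial-exporter"
    return PathClassification(label, float(imported), float(exported))
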