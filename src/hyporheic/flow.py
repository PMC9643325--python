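"""Saturated Darcy flow along a 1D hyporheic flow path.

Boundary stage differences are converted to a spatially uniform,
time-varying pore-water velocity: i_h = (h_up - h_dn)/L, q = K i_h,
v = q/n, with K = k rho g / mu the hydraulic conductivity recovered from
intrinsic permeability.  Flow is quasi-static (no storage term) and may
reverse sign; the transport stepper selects the inflow face from the
sign of v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydrology import HeadSeries

__all__ = [
    "WaterProperties",
    "FlowPathGeometry",
    "VelocitySeries",
    "conductivity_from_permeability",
    "velocity_series",
    "velocity_from_gradient",
]


@dataclass(frozen=True)
class WaterProperties:
    """Water at ~20 degC; configurable, the physics only needs rho*g/mu."""

    rho: float = 998.0       # kg/m^3
    g: float = 9.81          # m/s^2
    mu: float = 1.0e-3       # Pa s

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.g <= 0 or self.mu <= 0:
            raise ValueError("water properties must be positive")


@dataclass(frozen=True)
class FlowPathGeometry:
    """1D flow-path geometry: L x 1 m x 1 m column of 0.1 m cells."""

    length_m: float
    dx_m: float = 0.1
    porosity: float = 0.2
    permeability_m2: float = 2.26e-11

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.dx_m <= 0:
            raise ValueError("length and dx must be positive")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must lie in (0, 1)")
        if self.permeability_m2 <= 0:
            raise ValueError("permeability must be positive")
        ncells = self.length_m / self.dx_m
        if abs(ncells - round(ncells)) > 1e-9:
            raise ValueError("length must be an integer number of cells")
        if not 50 <= round(ncells) <= 700:
            raise ValueError("cell count out of supported range")

    @property
    def n_cells(self) -> int:
        return int(round(self.length_m / self.dx_m))

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx_m

    @property
    def cell_water_volume_L(self) -> float:
        """Pore-water volume of one cell (liters), 1 m x 1 m cross-section."""
        return self.dx_m * 1.0 * 1.0 * self.porosity * 1000.0


def conductivity_from_permeability(k_m2: float,
                                   water: WaterProperties | None = None) -> float:
    """Hydraulic conductivity K = k rho g / mu (m/s)."""
    if k_m2 <= 0:
        raise ValueError("permeability must be positive")
    w = water or WaterProperties()
    return k_m2 * w.rho * w.g / w.mu


@dataclass
class VelocitySeries:
    """Time-varying uniform flow along the path."""

    times_h: np.ndarray
    gradient: np.ndarray        # (h_up - h_dn)/L, m/m
    darcy_flux: np.ndarray      # q = K i, m/s
    pore_velocity: np.ndarray   # v = q/n, m/s

    def __post_init__(self) -> None:
        n = self.times_h.size
        if not (self.gradient.size == self.darcy_flux.size
                == self.pore_velocity.size == n):
            raise ValueError("velocity series arrays must be equal length")


def velocity_from_gradient(gradient, geom: FlowPathGeometry,
                           water: WaterProperties | None = None):
    """Pore velocity v = K i / n for a gradient (scalar or array)."""
    K = conductivity_from_permeability(geom.permeability_m2, water)
    return K * np.asarray(gradient, dtype=float) / geom.porosity


def velocity_series(heads: HeadSeries, geom: FlowPathGeometry,
                    water: WaterProperties | None = None) -> VelocitySeries:
    """Convert boundary heads to the uniform pore-velocity history.

    The gradient uses the geometry's path length, which may differ from
    the head series' separation when the same stage records force paths
    of different lengths (the head *difference* is what the dam sets).
    """
    K = conductivity_from_permeability(geom.permeability_m2, water)
    i_h = (heads.h_up - heads.h_dn) / geom.length_m
    q = K * i_h
    v = q / geom.porosity
    return VelocitySeries(heads.times_h.copy(), i_h, q, v)
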