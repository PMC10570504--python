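"""Quasi-1D generalized-Newtonian surrogate flow solver.

Stands in for a full 3-D CFD solve behind a pluggable contract: any callable
mapping a :class:`~vesselrom.geometry.VesselGeometry` to a
:class:`FlowSolution` that honours the same invariants (zero outlet pressure,
positive wall shear stress, downstream-non-increasing pressure) can be
registered and used by the pipeline in its place.

The surrogate applies fully developed tube-flow relations station by station:

* flow rate ``Q = U_in * pi * r(0)^2`` is fixed by the inlet (mass conservation),
* wall shear rate from the Poiseuille estimate ``gamma_w = 4 Q / (pi r^3)``,
* blood viscosity from the Carreau-Yasuda shear-thinning law,
* wall shear stress ``tau_w = rho * nu(gamma_w) * gamma_w``,
* pressure from the axial force balance ``dp/ds = -2 tau_w / r`` integrated
  upstream (trapezoidal rule) from the zero-pressure outlet.

All outputs are in Pa; geometry is taken in mm and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import VesselGeometry

__all__ = [
    "RheologyParams",
    "SolverConfig",
    "FlowSolution",
    "kinematic_viscosity",
    "wall_shear_rate",
    "solve_flow",
    "register_solver",
    "get_solver",
]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class RheologyParams:
    """Carreau-Yasuda model coefficients for blood.

    nu(gamma) = nu_inf + (nu_0 - nu_inf) * (1 + (tau*gamma)^alpha)^((n-1)/alpha)

    Defaults are the standard coronary-blood fit: ``nu_inf`` and ``nu_0`` the
    infinite- and zero-shear kinematic viscosities (m^2/s), ``tau`` the
    relaxation time (s), ``alpha`` the transition sharpness and ``n`` the
    power-law index (0 < n < 1 gives shear thinning).
    """

    nu_inf: float = 3.45e-6
    nu_0: float = 56e-6
    tau: float = 3.313
    alpha: float = 2.0
    n: float = 0.3568

    def __post_init__(self) -> None:
        if not (self.nu_0 > self.nu_inf > 0):
            raise ValueError("need nu_0 > nu_inf > 0")
        if self.tau <= 0 or self.alpha <= 0 or not 0 < self.n < 1:
            raise ValueError("need tau > 0, alpha > 0, 0 < n < 1")


@dataclass(frozen=True)
class SolverConfig:
    """Boundary conditions and fluid density.

    ``inlet_speed`` is the constant mean inflow velocity in cm/s (default
    100); outlet pressure is fixed at 0 Pa; ``density`` is blood density in
    kg/m^3 (default 1060).
    """

    inlet_speed: float = 100.0    # cm/s
    density: float = 1060.0       # kg/m^3

    def __post_init__(self) -> None:
        if self.inlet_speed <= 0 or self.density <= 0:
            raise ValueError("inlet speed and density must be positive")


@dataclass(frozen=True)
class FlowSolution:
    """Steady pressure (volume nodes) and WSS (surface nodes) for one mesh."""

    mesh_id: str
    pressure: np.ndarray          # (Nv,) Pa
    wss: np.ndarray               # (Ns,) Pa
    station_pressure: np.ndarray  # (n_axial,) Pa, per-station values
    station_wss: np.ndarray       # (n_axial,) Pa


def kinematic_viscosity(
    shear_rate: float | np.ndarray, params: RheologyParams = RheologyParams()
) -> float | np.ndarray:
    """Carreau-Yasuda kinematic viscosity at shear rate(s) gamma (1/s).

    Strictly decreasing in gamma, bounded by (nu_inf, nu_0]: equals nu_0 at
    zero shear and tends to nu_inf as gamma -> infinity.
    """
    gamma = np.asarray(shear_rate, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("shear rate must be non-negative")
    nu = params.nu_inf + (params.nu_0 - params.nu_inf) * (
        1.0 + (params.tau * gamma) ** params.alpha
    ) ** ((params.n - 1.0) / params.alpha)
    return float(nu) if np.isscalar(shear_rate) else nu


def wall_shear_rate(flow_rate: float | np.ndarray, radius: float | np.ndarray):
    """Poiseuille wall shear rate estimate gamma_w = 4 Q / (pi r^3) (SI units)."""
    q = np.asarray(flow_rate, dtype=float)
    r = np.asarray(radius, dtype=float)
    if np.any(q <= 0) or np.any(r <= 0):
        raise ValueError("flow rate and radius must be positive")
    out = 4.0 * q / (np.pi * r**3)
    return float(out) if np.isscalar(flow_rate) and np.isscalar(radius) else out


def solve_flow(
    geom: VesselGeometry,
    cfg: SolverConfig = SolverConfig(),
    rheo: RheologyParams = RheologyParams(),
) -> FlowSolution:
    """Solve the quasi-1D flow through one geometry.

    Per station i the wall shear stress is assigned to every surface node and
    the (radially uniform) pressure to every volume node.
    """
    s = geom.stations * MM                 # m
    r = geom.radius * MM                   # m
    u_in = cfg.inlet_speed * 1e-2          # m/s
    q = u_in * np.pi * r[0] ** 2           # m^3/s, constant along the vessel

    gamma_w = wall_shear_rate(q, r)        # (n_axial,)
    nu = kinematic_viscosity(gamma_w, rheo)
    tau_w = cfg.density * nu * gamma_w     # Pa

    # dp/ds = -2 tau_w / r, integrated upstream from p(L) = 0 (trapezoid)
    g = 2.0 * tau_w / r                    # Pa/m, positive
    ds = np.diff(s)
    seg = 0.5 * (g[:-1] + g[1:]) * ds
    p = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])

    return FlowSolution(
        mesh_id=geom.id,
        pressure=p[geom.volume_station_index],
        wss=tau_w[geom.surface_station_index],
        station_pressure=p,
        station_wss=tau_w,
    )


# ---------------------------------------------------------------------------
# pluggable solver registry

SolverFn = Callable[[VesselGeometry], FlowSolution]
_SOLVERS: dict[str, SolverFn] = {}


def register_solver(name: str, fn: SolverFn) -> None:
    """Register a backend mapping VesselGeometry -> FlowSolution under a name."""
    _SOLVERS[name] = fn


def get_solver(name: str = "quasi1d") -> SolverFn:
    try:
        return _SOLVERS[name]
    except KeyError:
        raise KeyError(f"unknown solver {name!r}; registered: {sorted(_SOLVERS)}")


register_solver("quasi1d", solve_flow)
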