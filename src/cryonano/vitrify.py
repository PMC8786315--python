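"""Plunge-cooling simulation: forced convection into liquid ethane.

Vitrification requires the sample to pass the glass-transition temperature
Tg (~136 K for amorphous water) faster than ice can crystallise.  During
plunging, the chip is cooled by forced convection from the surrounding
cryogen.  This module provides:

* a laminar flat-plate film coefficient, Nu = 0.664 Re^1/2 Pr^1/3 with
  Re = rho*v*L/mu and Pr = cp*mu/k, h = Nu*k/L;
* a lumped-capacitance cooling time for a thin layer, valid when the Biot
  number h*d/k << 1 (always the case for a nm-scale membrane):
  tau = rho*cp*d/(sides*h), t(Tg) = tau * ln((T0 - Tinf)/(Tg - Tinf));
* a 1D thickness-integrated finite-difference model of in-plane conduction
  along the observation membrane and its silicon base, with a two-sided
  convective sink:  rho*cp*d dT/dt = d/dx(k*d dT/dx) - 2h(T - Tinf),
  solved with implicit (backward Euler) time stepping to tolerate the
  extreme thickness contrast (20 nm membrane vs 100 µm base).

Default coolant properties approximate liquid ethane near 90-100 K
(rho = 650 kg/m^3, mu = 1.2e-3 Pa s, k = 0.25 W/(m K), cp = 2300 J/(kg K));
all properties are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

logger = logging.getLogger(__name__)

__all__ = [
    "MaterialProps",
    "CoolantProps",
    "CoolingResult",
    "SILICON_NITRIDE",
    "SILICON",
    "LIQUID_ETHANE",
    "film_heat_transfer_coeff",
    "biot_number",
    "lumped_cooling_time",
    "lumped_cooling_curve",
    "fd_cooling_profile",
]

#: Glass-transition temperature of amorphous (vitreous) water, K.
TG_WATER_K = 136.0


@dataclass(frozen=True)
class MaterialProps:
    """Solid material: density (kg/m^3), heat capacity (J/kg/K),
    thermal conductivity (W/m/K)."""

    name: str
    density: float
    cp: float
    k: float

    def __post_init__(self) -> None:
        if min(self.density, self.cp, self.k) <= 0:
            raise ValueError(f"material properties must be positive: {self}")


# Thin-film silicon nitride: k averaged over the cryogenic range for
# nm-scale membranes, well below the bulk value.
SILICON_NITRIDE = MaterialProps("SiN", density=3100.0, cp=700.0, k=2.3)
SILICON = MaterialProps("Si", density=2329.0, cp=700.0, k=130.0)


@dataclass(frozen=True)
class CoolantProps:
    """Coolant bath and flow conditions for the flat-plate correlation."""

    density: float = 650.0       # kg/m^3
    viscosity: float = 1.2e-3    # Pa s
    k: float = 0.25              # W/(m K)
    cp: float = 2300.0           # J/(kg K)
    T_inf_K: float = 90.0
    velocity: float = 1.5        # m/s (plunge speed)
    plate_length: float = 2e-3   # m (chip edge)

    def __post_init__(self) -> None:
        if min(self.density, self.viscosity, self.k, self.cp,
               self.T_inf_K, self.velocity, self.plate_length) <= 0:
            raise ValueError("all coolant properties must be positive")

    @property
    def reynolds(self) -> float:
        return self.density * self.velocity * self.plate_length / self.viscosity

    @property
    def prandtl(self) -> float:
        return self.cp * self.viscosity / self.k


LIQUID_ETHANE = CoolantProps()


@dataclass
class CoolingResult:
    """Temperature history with the time at which the probe location first
    cools below Tg (``time_below_Tg_s``; NaN if never reached)."""

    times_s: np.ndarray
    temperatures_K: np.ndarray  # (n_times,) lumped or (n_times, n_nodes) FD
    time_below_Tg_s: float
    Tg_K: float = TG_WATER_K
    x_m: np.ndarray | None = None
    h_W_m2K: float | None = None
    biot: float | None = None
    extras: dict = field(default_factory=dict)


def film_heat_transfer_coeff(coolant: CoolantProps = LIQUID_ETHANE) -> float:
    """Average film coefficient h (W/m^2/K) from the laminar flat-plate
    correlation Nu = 0.664 Re^1/2 Pr^1/3."""
    re, pr = coolant.reynolds, coolant.prandtl
    if re > 5e5:
        logger.warning(
            "Re = %.3g exceeds the laminar flat-plate limit 5e5; "
            "correlation underestimates h", re,
        )
    nu = 0.664 * np.sqrt(re) * pr ** (1.0 / 3.0)
    return float(nu * coolant.k / coolant.plate_length)


def biot_number(h: float, thickness_m: float, mat: MaterialProps) -> float:
    """Bi = h*d/k across the layer thickness."""
    return h * thickness_m / mat.k


def lumped_cooling_time(
    layer_thickness_m: float,
    mat: MaterialProps,
    h: float,
    sides: int = 2,
    T0_K: float = 293.15,
    Tg_K: float = TG_WATER_K,
    T_inf_K: float = 90.0,
) -> float:
    """Time (s) for a thin layer to cool from T0 to Tg by convection.

    Lumped capacitance: tau = rho*cp*d/(sides*h), time = tau * ln((T0 -
    Tinf)/(Tg - Tinf)).  Emits a warning if the Biot number exceeds 0.1
    (lumped assumption marginal).
    """
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if Tg_K <= T_inf_K:
        raise ValueError(
            f"Tg = {Tg_K} K <= coolant temperature {T_inf_K} K: never reached"
        )
    if T0_K < Tg_K:
        return 0.0
    bi = biot_number(h, layer_thickness_m, mat)
    if bi > 0.1:
        logger.warning("Biot number %.3g > 0.1: lumped approximation is marginal", bi)
    tau = mat.density * mat.cp * layer_thickness_m / (sides * h)
    return float(tau * np.log((T0_K - T_inf_K) / (Tg_K - T_inf_K)))


def lumped_cooling_curve(
    layer_thickness_m: float,
    mat: MaterialProps,
    h: float,
    sides: int = 2,
    T0_K: float = 293.15,
    T_inf_K: float = 90.0,
    t_end_s: float = 2e-5,
    n_times: int = 200,
    Tg_K: float = TG_WATER_K,
) -> CoolingResult:
    """Exponential lumped-capacitance temperature history."""
    tau = mat.density * mat.cp * layer_thickness_m / (sides * h)
    t = np.linspace(0.0, t_end_s, n_times)
    T = T_inf_K + (T0_K - T_inf_K) * np.exp(-t / tau)
    t_tg = (
        lumped_cooling_time(layer_thickness_m, mat, h, sides, T0_K, Tg_K, T_inf_K)
        if T.min() <= Tg_K else float("nan")
    )
    return CoolingResult(
        times_s=t, temperatures_K=T, time_below_Tg_s=t_tg, Tg_K=Tg_K,
        h_W_m2K=h, biot=biot_number(h, layer_thickness_m, mat),
    )


def fd_cooling_profile(
    regions: list[tuple[float, MaterialProps, float]] | None = None,
    h: float | None = None,
    coolant: CoolantProps = LIQUID_ETHANE,
    T0_K: float = 293.15,
    t_end_s: float = 2e-5,
    n_nodes: int = 201,
    dt_s: float | None = None,
    Tg_K: float = TG_WATER_K,
    probe: str = "membrane_center",
) -> CoolingResult:
    """Implicit 1D finite-difference cooling of the membrane/base layup.

    ``regions`` is a list of ``(length_m, material, thickness_m)`` segments
    along the profile line; the default layup is a 50 µm SiN observation
    membrane 20 nm thick flanked by 975 µm of 100 µm-thick silicon base on
    each side.  The thickness-integrated heat equation

        rho*cp*d dT/dt = d/dx(k*d dT/dx) - 2h(T - Tinf)

    is discretised with harmonic-mean face conductances and backward-Euler
    time stepping (unconditionally stable under the thickness contrast).
    ``time_below_Tg_s`` is found at the probe node ("membrane_center" or
    "base_center") by linear interpolation between steps.
    """
    if regions is None:
        regions = [
            (975e-6, SILICON, 100e-6),
            (50e-6, SILICON_NITRIDE, 20e-9),
            (975e-6, SILICON, 100e-6),
        ]
    if n_nodes < 50:
        raise ValueError("n_nodes must be >= 50 to resolve the layup")
    if h is None:
        h = film_heat_transfer_coeff(coolant)
    T_inf = coolant.T_inf_K

    total_len = sum(r[0] for r in regions)
    x = np.linspace(0.0, total_len, n_nodes)
    dx = x[1] - x[0]
    rho_cp_d = np.empty(n_nodes)
    k_d = np.empty(n_nodes)
    region_of = np.empty(n_nodes, dtype=int)
    bounds = np.cumsum([0.0] + [r[0] for r in regions])
    for i, xi in enumerate(x):
        j = min(np.searchsorted(bounds, xi, side="right") - 1, len(regions) - 1)
        length, mat, d = regions[j]
        rho_cp_d[i] = mat.density * mat.cp * d
        k_d[i] = mat.k * d
        region_of[i] = j

    if dt_s is None:
        # resolve the fastest lumped time constant in the layup
        tau_min = (rho_cp_d / (2.0 * h)).min()
        dt_s = min(tau_min / 100.0, t_end_s / 400.0)
    n_steps = int(np.ceil(t_end_s / dt_s))
    dt = t_end_s / n_steps

    # harmonic-mean face conductances k*d at i+1/2
    kf = 2.0 * k_d[:-1] * k_d[1:] / (k_d[:-1] + k_d[1:])

    # backward Euler: (C/dt + K + S) T^{n+1} = C/dt T^n + S T_inf
    # with insulated (symmetry) ends; assemble banded tridiagonal form.
    C = rho_cp_d / dt
    S = 2.0 * h
    ab = np.zeros((3, n_nodes))
    ab[0, 1:] = -kf / dx**2                     # upper diagonal
    ab[2, :-1] = -kf / dx**2                    # lower diagonal
    ab[1, :] = C + S
    ab[1, :-1] += kf / dx**2
    ab[1, 1:] += kf / dx**2

    T = np.full(n_nodes, float(T0_K))
    # the membrane is the thinnest region in the layup
    membrane_nodes = np.flatnonzero(region_of == int(np.argmin([r[2] for r in regions])))
    if probe == "membrane_center":
        probe_idx = int(membrane_nodes[len(membrane_nodes) // 2]) if len(membrane_nodes) else n_nodes // 2
    elif probe == "base_center":
        base_nodes = np.flatnonzero(region_of == 0)
        probe_idx = int(base_nodes[len(base_nodes) // 2])
    else:
        raise ValueError(f"unknown probe {probe!r}")

    times = [0.0]
    history = [T.copy()]
    t_tg = float("nan")
    for step in range(1, n_steps + 1):
        rhs = C * T + S * T_inf
        T_new = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(T_new)):
            raise FloatingPointError("finite-difference step produced non-finite values")
        t_prev, t_now = (step - 1) * dt, step * dt
        if np.isnan(t_tg) and T_new[probe_idx] <= Tg_K < T[probe_idx]:
            frac = (T[probe_idx] - Tg_K) / (T[probe_idx] - T_new[probe_idx])
            t_tg = t_prev + frac * dt
        T = T_new
        times.append(t_now)
        history.append(T.copy())

    return CoolingResult(
        times_s=np.array(times),
        temperatures_K=np.array(history),
        time_below_Tg_s=t_tg,
        Tg_K=Tg_K,
        x_m=x,
        h_W_m2K=h,
        biot=float(biot_number(h, max(r[2] for r in regions), SILICON)),
        extras={"probe_idx": probe_idx, "dt_s": dt, "region_of": region_of},
    )
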