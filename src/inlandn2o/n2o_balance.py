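"""Dissolved-N2O mass balance per water element.

The per-step change of dissolved N2O mass is the sum of five audited terms:

    dM/dt = F_a + Y_water + D - R - E

advective net flux, in-water production (from nitrification and
denitrification substrates), rain deposition at the atmospheric equilibrium
concentration, benthic reduction to N2, and air-water efflux.  Reduction is
strongest when nitrate is depleted, which lets a water body draw N2O below
atmospheric equilibrium and act as a net sink (negative efflux).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GasParams, RateParams

__all__ = [
    "N2OState",
    "FluxBreakdown",
    "production",
    "rain_deposition",
    "reduction",
    "efflux",
    "equilibrium_concentration",
    "gas_transfer_velocity",
    "step_n2o",
]

SECONDS_PER_DAY = 86_400.0
#: grams of N per mole of N2O (two N atoms)
G_N_PER_MOL_N2O = 28.0134

# Solubility-function coefficients for N2O in fresh water (salinity terms
# dropped), yielding F in mol L-1 atm-1 from the absolute temperature:
#   ln F = a1 + a2*(100/T) + a3*ln(T/100) + a4*(T/100)^2
_SOL_A1 = -165.8806
_SOL_A2 = 222.8743
_SOL_A3 = 92.0792
_SOL_A4 = -1.48425


@dataclass
class N2OState:
    """Per-element dissolved N2O mass (g N)."""

    mass: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "N2OState":
        return cls(np.zeros(n))

    def concentration(self, volume: np.ndarray) -> np.ndarray:
        return np.divide(self.mass, volume, out=np.zeros_like(self.mass), where=volume > 0)


@dataclass
class FluxBreakdown:
    """The five audited terms of the balance (g N d-1), one step.

    Invariant: dM/dt == f_a + y_water + d_dep - r_red - e_efflux at machine
    precision for every element.
    """

    f_a: np.ndarray
    y_water: np.ndarray
    d_dep: np.ndarray
    r_red: np.ndarray
    e_efflux: np.ndarray

    def net(self) -> np.ndarray:
        return self.f_a + self.y_water + self.d_dep - self.r_red - self.e_efflux


def production(flux_nit, flux_den, y_nit: float, y_den: float):
    """In-water N2O production (g N d-1): y_nit*flux_nit + y_den*flux_den."""
    if not (0.0 <= y_nit <= 1.0 and 0.0 <= y_den <= 1.0):
        raise ValueError("yields must lie in [0, 1]")
    return y_nit * np.asarray(flux_nit) + y_den * np.asarray(flux_den)


def rain_deposition(rain_volume, c_eq):
    """N2O delivered by rain (g N d-1): rain volume times equilibrium concentration."""
    rain_volume = np.asarray(rain_volume, dtype=float)
    if np.any(rain_volume < 0):
        raise ValueError("rain_volume must be >= 0")
    return rain_volume * np.asarray(c_eq)


def reduction(
    n2o_conc, no3_conc, bed_area, temperature, dt: float, params: RateParams
):
    """Benthic N2O -> N2 reduction flux (g N d-1), nitrate-inhibited.

    Flux = v_red * f_T * [N2O] * bed_area * k_half/(k_half + [NO3]); the
    inhibition factor makes reduction strongest when nitrate is depleted
    (N2O becomes the preferred electron acceptor) and vanish when nitrate is
    plentiful.  The caller caps the integrated flux at the available mass.
    """
    from .aquatic_nitrogen import temperature_factor

    f_t = temperature_factor(temperature, params)
    no3 = np.asarray(no3_conc, dtype=float)
    denom = params.k_half_no3 + no3
    inhibition = np.divide(params.k_half_no3, denom,
                           out=np.ones_like(no3), where=denom > 0)
    return params.v_red * SECONDS_PER_DAY * f_t * np.asarray(n2o_conc) * np.asarray(bed_area) * inhibition


def efflux(n2o_conc, c_eq, k_gas, surface_area):
    """Air-water N2O flux (g N d-1), positive to the atmosphere.

    k_gas * area * (concentration - equilibrium); negative values are influx
    (the water body is a net atmospheric N2O sink).
    """
    k_gas = np.asarray(k_gas, dtype=float)
    area = np.asarray(surface_area, dtype=float)
    if np.any(k_gas < 0):
        raise ValueError("k_gas must be >= 0")
    if np.any(area <= 0):
        raise ValueError("surface_area must be > 0")
    return k_gas * area * (np.asarray(n2o_conc) - np.asarray(c_eq))


def equilibrium_concentration(temperature, x_atm_ppb):
    """Dissolved N2O concentration (g N m-3) in equilibrium with the atmosphere.

    Henry-type solubility of N2O in fresh water (moist-air solubility
    function, salinity 0), linear in the atmospheric mixing ratio and
    decreasing with temperature.
    """
    x = np.asarray(x_atm_ppb, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_atm_ppb must be >= 0")
    t_k = np.asarray(temperature, dtype=float) + 273.15
    ln_f = (
        _SOL_A1
        + _SOL_A2 * (100.0 / t_k)
        + _SOL_A3 * np.log(t_k / 100.0)
        + _SOL_A4 * (t_k / 100.0) ** 2
    )
    f_mol_per_l_atm = np.exp(ln_f)
    # mol L-1 atm-1 -> g N m-3 at x ppb partial pressure
    out = f_mol_per_l_atm * 1000.0 * (x * 1e-9) * G_N_PER_MOL_N2O
    return out if out.ndim else float(out)


def gas_transfer_velocity(
    element_kind: str,
    wind: float,
    depth,
    velocity: float,
    slope,
    params: GasParams,
):
    """Piston velocity k (m d-1) for the air-water interface.

    Lentic elements use a quadratic-in-wind form k = a + b * wind^2; lotic
    elements a hydraulic form k = base + coef * (velocity*slope)^exp *
    depth^depth_exp.  Coefficients are configuration.
    """
    if wind < 0 or velocity < 0:
        raise ValueError("wind and velocity must be >= 0")
    if element_kind == "lentic":
        return params.k_lentic_base + params.k_lentic_wind2 * wind**2
    if element_kind == "lotic":
        depth = np.maximum(np.asarray(depth, dtype=float), 1e-3)
        energy = np.maximum(velocity * np.asarray(slope, dtype=float), 0.0)
        k = params.k_lotic_base + params.k_lotic_coef * energy**params.k_lotic_exp * depth**params.k_lotic_depth_exp
        return k if k.ndim else float(k)
    raise ValueError(f"element_kind must be 'lentic' or 'lotic', got {element_kind!r}")


def step_n2o(
    *,
    mass: np.ndarray,
    volume: np.ndarray,
    f_a: np.ndarray,
    flux_nit: np.ndarray,
    flux_den: np.ndarray,
    no3_conc: np.ndarray,
    bed_area: np.ndarray,
    surface_area: np.ndarray,
    k_gas: np.ndarray,
    c_eq: np.ndarray,
    rain_volume: np.ndarray,
    temperature: np.ndarray,
    rates: RateParams,
    dt: float = 1.0,
) -> tuple[np.ndarray, FluxBreakdown]:
    """One operator-split daily update of dissolved N2O for a set of elements.

    Order (fixed): advection (already applied upstream, reported via
    ``f_a``) -> production + rain deposition -> reduction -> efflux.
    Reduction and (positive) efflux are limited so the mass never goes
    negative; the returned breakdown satisfies the balance identity exactly.
    """
    mass = mass.astype(float).copy()
    y = production(flux_nit, flux_den, rates.y_nit, rates.y_den)
    d = rain_deposition(rain_volume, c_eq)
    mass += (y + d) * dt

    conc = np.divide(mass, volume, out=np.zeros_like(mass), where=volume > 0)
    r = reduction(conc, no3_conc, bed_area, temperature, dt, rates)
    r = np.minimum(r, mass / dt)
    mass -= r * dt

    conc = np.divide(mass, volume, out=np.zeros_like(mass), where=volume > 0)
    e = efflux(conc, c_eq, k_gas, surface_area)
    e = np.minimum(e, mass / dt)  # positive efflux cannot remove more than present
    mass -= e * dt

    return mass, FluxBreakdown(f_a=np.asarray(f_a, dtype=float), y_water=y * np.ones_like(mass),
                               d_dep=d * np.ones_like(mass), r_red=r, e_efflux=e)
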