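"""Kinetics of the four transported nitrogen species (NO3, NH4, DON, PON).

All transformations are first-order with a Q10 temperature response and a
cold-season cutoff; benthic denitrification is a Michaelis-Menten-limited
uptake-velocity flux.  Functions operate element-wise on scalars or numpy
arrays and return the transformed amounts (g N over the step) so the caller
can keep an exact mass ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RateParams

__all__ = [
    "NitrogenState",
    "temperature_factor",
    "decompose_don",
    "settle_pon",
    "nitrify",
    "denitrify",
]

SECONDS_PER_DAY = 86_400.0
SPECIES = ("no3", "nh4", "don", "pon")


@dataclass
class NitrogenState:
    """Per-element masses (g N) of the four transported species."""

    mass_no3: np.ndarray
    mass_nh4: np.ndarray
    mass_don: np.ndarray
    mass_pon: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "NitrogenState":
        return cls(*(np.zeros(n) for _ in SPECIES))

    def total(self) -> float:
        return float(self.mass_no3.sum() + self.mass_nh4.sum()
                     + self.mass_don.sum() + self.mass_pon.sum())

    def concentration(self, species: str, volume: np.ndarray) -> np.ndarray:
        """g N m-3; zero where there is no water (mass must then be zero too)."""
        mass = getattr(self, f"mass_{species}")
        return np.divide(mass, volume, out=np.zeros_like(mass), where=volume > 0)


def temperature_factor(
    temperature: np.ndarray | float, params: RateParams
) -> np.ndarray | float:
    """Q10 multiplier q10**((T - t_ref)/10), zeroed below the cold cutoff.

    The cutoff stands in for ice cover: transformation stops when the water
    temperature proxy drops to ~0 degC.
    """
    t = np.asarray(temperature, dtype=float)
    f = params.q10 ** ((t - params.t_ref) / 10.0)
    f = np.where(t <= params.cold_cutoff_c, 0.0, f)
    return f if f.ndim else float(f)


def decompose_don(mass_don, temperature, dt: float, params: RateParams):
    """DON -> NH4 transfer over the step: M * (1 - exp(-k_dec * f_T * dt))."""
    f_t = temperature_factor(temperature, params)
    return np.asarray(mass_don) * -np.expm1(-params.k_dec * f_t * dt)


def settle_pon(mass_pon, depth, v_settle: float, dt: float):
    """PON mass leaving the water column: fraction 1 - exp(-(v/h) * dt).

    ``depth`` must be > 0; deep water settles a vanishing fraction.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be > 0")
    frac = -np.expm1(-(v_settle / depth) * dt)
    return np.asarray(mass_pon) * frac


def nitrify(mass_nh4, temperature, dt: float, params: RateParams):
    """NH4 mass oxidised over the step (first order, Q10-scaled).

    The caller routes (1 - y_nit) of it to NO3 and hands y_nit to the N2O
    production term.
    """
    f_t = temperature_factor(temperature, params)
    return np.asarray(mass_nh4) * -np.expm1(-params.k_nit * f_t * dt)


def denitrify(mass_no3, volume, bed_area, temperature, dt: float, params: RateParams):
    """NO3 mass denitrified over the step via a benthic uptake-velocity flux.

    Potential flux = v_den * f_T * [NO3] * bed_area damped by the
    Michaelis-Menten factor k_half / ([NO3] + k_half), so the flux is linear
    in concentration when NO3 is scarce and saturates (at v_den * f_T *
    k_half * bed_area) when NO3 is plentiful; capped at the available mass.
    Set ``k_half_no3 = inf`` for the undamped linear law.

    The caller splits the removed NO3 into an N2O share (y_den) and an N2
    share (1 - y_den).
    """
    mass = np.asarray(mass_no3, dtype=float)
    volume = np.asarray(volume, dtype=float)
    conc = np.divide(mass, volume, out=np.zeros_like(mass * 1.0), where=volume > 0)
    f_t = temperature_factor(temperature, params)
    if np.isinf(params.k_half_no3):
        damping = 1.0
    else:
        denom = conc + params.k_half_no3
        damping = np.divide(params.k_half_no3, denom,
                            out=np.zeros_like(conc), where=denom > 0)
    potential = params.v_den * SECONDS_PER_DAY * f_t * conc * np.asarray(bed_area) * damping
    return np.minimum(potential * dt, mass)
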