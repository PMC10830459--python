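"""Run configuration: every tunable parameter of the simulator with defaults.

All rate constants are calibration knobs; the values below are defensible
order-of-magnitude defaults for inland-water nitrogen cycling, not fitted
constants.  Unknown keys in a config file are rejected so that typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "RateParams",
    "HydroParams",
    "GasParams",
    "AtmosphereParams",
    "RunConfig",
    "ConfigError",
]

V_DEN_BOUNDS = (3e-8, 2e-6)  # m s-1, admissible benthic denitrification uptake velocity


class ConfigError(ValueError):
    """Raised for malformed configuration input (unknown or invalid keys)."""


@dataclass(frozen=True)
class RateParams:
    """First-order kinetic parameters for in-water nitrogen transformations.

    Rates are per day unless noted; uptake velocities (``v_den``, ``v_red``)
    are in m s-1 as conventionally reported for benthic fluxes.
    """

    k_dec: float = 0.01          # d-1, DON -> NH4 decomposition
    v_settle: float = 0.5        # m d-1, PON settling velocity
    k_nit: float = 0.05          # d-1, NH4 -> NO3 nitrification
    v_den: float = 3e-7          # m s-1, benthic denitrification uptake velocity
    v_red: float = 1e-7          # m s-1, benthic N2O reduction uptake velocity
    q10: float = 2.0             # temperature sensitivity
    t_ref: float = 20.0          # degC, reference temperature of the rate constants
    k_half_no3: float = 0.1      # g N m-3, half-saturation for NO3 limitation
    cold_cutoff_c: float = 0.5   # degC, water temperature below which biology stops
    sed_remin_k: float = 0.005   # d-1, labile sediment PON remineralisation
    sed_burial_frac: float = 0.5  # fraction of settled PON permanently buried
    y_nit: float = 0.001         # N2O yield of nitrification
    y_den: float = 0.005         # N2O yield of denitrification (rest goes to N2)

    def __post_init__(self) -> None:
        lo, hi = V_DEN_BOUNDS
        if not (lo <= self.v_den <= hi):
            raise ConfigError(
                f"v_den={self.v_den!r} outside admissible bounds [{lo}, {hi}] m s-1"
            )
        for name in ("k_dec", "v_settle", "k_nit", "v_red", "sed_remin_k"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.q10 < 1:
            raise ConfigError("q10 must be >= 1")
        for name in ("y_nit", "y_den", "sed_burial_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class HydroParams:
    """Water-routing parameters."""

    celerity_ms: float = 1.0        # m s-1, kinematic wave celerity for reaches
    evap_m_per_day: float = 0.0     # open-water evaporation rate
    resolution_deg: float = 0.5     # grid resolution used for the size classification
    temp_smoothing_days: float = 30.0  # e-folding window of the water-temperature proxy
    min_depth_m: float = 0.01       # floor for concentration/settling depth

    def __post_init__(self) -> None:
        if self.celerity_ms <= 0:
            raise ConfigError("celerity_ms must be > 0")
        if self.resolution_deg <= 0:
            raise ConfigError("resolution_deg must be > 0")


@dataclass(frozen=True)
class GasParams:
    """Air-water gas-transfer parameterisation (piston velocities, m d-1)."""

    k_lentic_base: float = 0.5    # m d-1 at zero wind
    k_lentic_wind2: float = 0.026  # m d-1 per (m s-1)^2
    k_lotic_base: float = 1.0     # m d-1 floor for flowing water
    k_lotic_coef: float = 50.0    # m d-1 scale on (velocity*slope)^exp
    k_lotic_exp: float = 0.5
    k_lotic_depth_exp: float = -0.5
    wind_default: float = 3.0     # m s-1 when no wind forcing is supplied


@dataclass(frozen=True)
class AtmosphereParams:
    """Atmospheric N2O mixing-ratio forcing (linear ramp between anchors)."""

    n2o_ppb_start: float = 273.0
    n2o_ppb_end: float = 332.0
    year_start: int = 1850
    year_end: int = 2019

    def mixing_ratio(self, year: float) -> float:
        """Atmospheric N2O mixing ratio (ppb) for a calendar year, clamped."""
        if year <= self.year_start:
            return self.n2o_ppb_start
        if year >= self.year_end:
            return self.n2o_ppb_end
        frac = (year - self.year_start) / (self.year_end - self.year_start)
        return self.n2o_ppb_start + frac * (self.n2o_ppb_end - self.n2o_ppb_start)


def _build(cls, data: dict[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: parameter blocks plus run metadata."""

    rates: RateParams = field(default_factory=RateParams)
    hydro: HydroParams = field(default_factory=HydroParams)
    gas: GasParams = field(default_factory=GasParams)
    atmosphere: AtmosphereParams = field(default_factory=AtmosphereParams)
    seed: int = 0
    output_dir: str = "output"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        blocks = {
            "rates": RateParams,
            "hydro": HydroParams,
            "gas": GasParams,
            "atmosphere": AtmosphereParams,
        }
        kwargs: dict[str, Any] = {}
        for key, sub in blocks.items():
            if key in data:
                kwargs[key] = _build(sub, data.pop(key) or {}, key)
        allowed = {"seed", "output_dir"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
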