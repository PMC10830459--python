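"""Simulation protocol: equilibrium, spin-up, transients, attribution, ensembles.

The full protocol mirrors the staged design of transient watershed
simulations: (1) an equilibrium run repeating first-year forcing until all
state pools settle, (2) a 30-year spin-up drawing random 1850s climate
years, (3) a natural-flow transient with dams deactivated followed by
dam-managed transients, and (4) five factorial experiments that each hold
one driver at its first-year value.  Factor effects are attributed by
differencing each factorial run against the all-transient run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .network import RoutingNetwork, build_network
from .simulator import DailyForcing, Simulator
from .synthetic_data import (
    DAYS_PER_YEAR,
    ForcingSeries,
    LoadResponseParams,
    NetworkTables,
    terrestrial_loads,
)

__all__ = [
    "FACTORS",
    "Scenario",
    "ScenarioResult",
    "ConvergenceReport",
    "equilibrium_run",
    "spinup_run",
    "transient_run",
    "run_full_protocol",
    "attribute",
    "uncertainty_ensemble",
    "DEFAULT_PERTURBATIONS",
    "decade_of",
]

#: the five environmental drivers of the factorial design
FACTORS = ("climate", "co2", "landuse", "ndep", "ag_n")

#: load-perturbation amplitudes of the uncertainty ensemble
DEFAULT_PERTURBATIONS = {"no3": 0.22, "nh4": 0.50, "don": 0.37, "pon": 0.26}


@dataclass(frozen=True)
class Scenario:
    """One member of the factorial design.

    S1 is the all-transient run (no factor fixed); S2-S6 each hold exactly
    one driver at its first-year value.  ``dams`` switches reservoir
    operation; ``load_multipliers`` supports the uncertainty ensemble.
    """

    scenario_id: str
    fixed_factors: frozenset[str] = frozenset()
    dams: str = "on"
    seed: int = 0
    load_multipliers: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        unknown = set(self.fixed_factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors {sorted(unknown)}; valid: {FACTORS}")
        if self.dams not in ("on", "off"):
            raise ValueError("dams must be 'on' or 'off'")

    @classmethod
    def factorial_set(cls, seed: int = 0) -> dict[str, "Scenario"]:
        """S1 (all transient) plus one fixed-factor scenario per driver."""
        scenarios = {"S1": cls("S1", frozenset(), "on", seed)}
        for i, factor in enumerate(FACTORS, start=2):
            scenarios[f"S{i}"] = cls(f"S{i}", frozenset({factor}), "on", seed)
        return scenarios


@dataclass
class ConvergenceReport:
    converged: bool
    years: int
    residual: float
    tol: float


@dataclass
class ScenarioResult:
    """Annual emissions by (kind, size class, country) for one scenario."""

    scenario: Scenario
    annual: pd.DataFrame  # columns: year, kind, size_class, country, emission_gN

    GG = 1e-9  # g N -> Gg N

    def annual_total(self, kinds: Optional[tuple[str, ...]] = None) -> pd.Series:
        """Total emissions per year in Gg N yr-1, optionally filtered by kind."""
        df = self.annual
        if kinds is not None:
            df = df[df.kind.isin(kinds)]
        return df.groupby("year").emission_gN.sum() * self.GG

    def decadal(self, kinds: Optional[tuple[str, ...]] = None) -> pd.DataFrame:
        """Decadal mean +/- standard deviation of the annual totals (Gg N yr-1)."""
        totals = self.annual_total(kinds)
        dec = totals.groupby(totals.index.map(decade_of))
        return pd.DataFrame({"mean_GgN": dec.mean(), "std_GgN": dec.std(ddof=0),
                             "n_years": dec.count()})

    def by_group(self) -> pd.DataFrame:
        """Annual emissions per (kind, size_class) group, Gg N yr-1."""
        g = self.annual.groupby(["year", "kind", "size_class"]).emission_gN.sum()
        return (g * self.GG).reset_index(name="emission_GgN")

    def country_annual(self, kinds: Optional[tuple[str, ...]] = None) -> pd.DataFrame:
        df = self.annual
        if kinds is not None:
            df = df[df.kind.isin(kinds)]
        g = df.groupby(["year", "country"]).emission_gN.sum()
        return (g * self.GG).reset_index(name="emission_GgN")


def decade_of(year: int) -> int:
    """Decade label: 1850s = 1850-1859, ..., 2010s = 2010-2019."""
    return (int(year) // 10) * 10


def _frozen_kwargs(scenario: Scenario, first_year: int) -> dict[str, int]:
    mapping = {"climate": "climate_year", "co2": "co2_year", "landuse": "landuse_year",
               "ndep": "ndep_year", "ag_n": "agn_year"}
    return {mapping[f]: first_year for f in scenario.fixed_factors}


def _run_year(
    sim: Simulator,
    fs: ForcingSeries,
    year: int,
    load_params: LoadResponseParams,
    *,
    climate_year: Optional[int] = None,
    frozen: Optional[dict[str, int]] = None,
    load_multipliers: Optional[dict[str, float]] = None,
    atm_year: Optional[int] = None,
) -> np.ndarray:
    """Step one simulated year; returns per-group summed efflux (g N)."""
    kwargs = dict(frozen or {})
    if climate_year is not None:
        kwargs["climate_year"] = climate_year
    runoff, loads, climate = terrestrial_loads(
        fs, year, sim.cell_area, load_params,
        load_multipliers=load_multipliers, **kwargs)
    # the atmospheric N2O ramp travels with the greenhouse-gas factor: it is
    # frozen alongside CO2 in factorial runs
    x_atm = sim.config.atmosphere.mixing_ratio(atm_year if atm_year is not None else year)
    for d in range(DAYS_PER_YEAR):
        sim.step(DailyForcing(
            runoff=runoff[d], loads=loads[d], air_temp=climate["tmean"][d],
            precip_m=climate["precip_m"][d], x_atm_ppb=x_atm, year=year))
    return sim.pop_annual_efflux()


def equilibrium_run(
    sim: Simulator,
    fs: ForcingSeries,
    load_params: Optional[LoadResponseParams] = None,
    tol: float = 1e-4,
    max_years: int = 500,
) -> ConvergenceReport:
    """Repeat first-year forcing until every state pool stops changing.

    Convergence: the maximum relative interannual change over all pools
    (water storage, the four N species, dissolved N2O, labile sediment)
    drops below ``tol``.  On non-convergence a warning carries the residual
    and the state is still usable.
    """
    lp = load_params or LoadResponseParams()
    first = fs.start
    pool_keys = ("storage", "no3", "nh4", "don", "pon", "n2o", "sediment")
    prev = sim.snapshot()
    residual = np.inf
    years = 0
    for years in range(1, max_years + 1):
        _run_year(sim, fs, first, lp)
        snap = sim.snapshot()
        # element-wise L1 change per pool, so slow small elements are not
        # masked by large fast ones
        residual = max(
            float(np.abs(snap[k] - prev[k]).sum())
            / max(float(np.abs(snap[k]).sum()), 1e-9)
            for k in pool_keys
        )
        prev = snap
        if residual < tol:
            return ConvergenceReport(True, years, residual, tol)
    warnings.warn(
        f"equilibrium run did not converge in {max_years} years "
        f"(residual {residual:.3e} > tol {tol:.1e})", stacklevel=2)
    return ConvergenceReport(False, years, residual, tol)


def spinup_run(
    sim: Simulator,
    fs: ForcingSeries,
    load_params: Optional[LoadResponseParams] = None,
    years: int = 30,
    seed: int = 0,
) -> list[int]:
    """Spin up with climate years drawn uniformly (with replacement) from the 1850s.

    Non-climate drivers stay at their first-year values.  Returns the drawn
    year sequence so it can be recorded in the run manifest.
    """
    lp = load_params or LoadResponseParams()
    pool = [y for y in range(fs.start, min(fs.start + 10, fs.end + 1))]
    rng = np.random.default_rng(seed)
    drawn = [int(rng.choice(pool)) for _ in range(years)]
    frozen = _frozen_kwargs(Scenario("Sx", frozenset(FACTORS)), fs.start)
    for y in drawn:
        _run_year(sim, fs, fs.start, lp, climate_year=y, frozen=frozen)
    return drawn


def transient_run(
    sim: Simulator,
    fs: ForcingSeries,
    scenario: Scenario,
    load_params: Optional[LoadResponseParams] = None,
    start: Optional[int] = None,
    end: Optional[int] = None,
) -> ScenarioResult:
    """Run one scenario over the transient period and collect annual aggregates."""
    lp = load_params or LoadResponseParams()
    start = fs.start if start is None else start
    end = fs.end if end is None else end
    sim.natural_flow = scenario.dams == "off"
    sim._dam_year = None  # force dam-mask refresh under the new flag
    frozen = _frozen_kwargs(scenario, fs.start)
    atm_year = fs.start if "co2" in scenario.fixed_factors else None
    rows = []
    for year in range(start, end + 1):
        sums = _run_year(sim, fs, year, lp, frozen=frozen,
                         load_multipliers=scenario.load_multipliers,
                         atm_year=atm_year)
        for (kind, size, country), v in zip(sim.group_keys, sums):
            rows.append((year, kind, size, country, v))
    annual = pd.DataFrame(rows, columns=["year", "kind", "size_class", "country",
                                         "emission_gN"])
    return ScenarioResult(scenario=scenario, annual=annual)


@dataclass
class ProtocolResult:
    """Everything produced by one full staged protocol run."""

    results: dict[str, ScenarioResult]
    natural: Optional[ScenarioResult]
    equilibrium: ConvergenceReport
    spinup_years: list[int]
    manifest: dict = field(default_factory=dict)


def run_full_protocol(
    tables: NetworkTables,
    fs: ForcingSeries,
    config: Optional[RunConfig] = None,
    load_params: Optional[LoadResponseParams] = None,
    seed: int = 0,
    scenarios: Optional[dict[str, Scenario]] = None,
    eq_tol: float = 1e-4,
    eq_max_years: int = 500,
    spinup_years: int = 30,
    include_natural: bool = True,
) -> ProtocolResult:
    """Equilibrium -> spin-up -> natural flow -> factorial transients.

    All factorial runs branch from the common post-spin-up state.  The
    natural-flow (dams off) transient runs first, as the managed runs'
    baseline diagnostic.
    """
    config = config or RunConfig()
    lp = load_params or LoadResponseParams()
    network = build_network(tables.cells, tables.reaches, tables.bodies,
                            resolution_deg=config.hydro.resolution_deg)
    sim = Simulator(network, config)
    report = equilibrium_run(sim, fs, lp, tol=eq_tol, max_years=eq_max_years)
    drawn = spinup_run(sim, fs, lp, years=spinup_years, seed=seed)
    branch = sim.snapshot()

    scenarios = scenarios or Scenario.factorial_set(seed)
    natural = None
    if include_natural:
        sim.restore(branch)
        natural = transient_run(
            sim, fs, Scenario("S1-natural", frozenset(), "off", seed), lp)
    results: dict[str, ScenarioResult] = {}
    for sid, scenario in scenarios.items():
        sim.restore(branch)
        results[sid] = transient_run(sim, fs, scenario, lp)

    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "spinup_climate_years": drawn,
        "equilibrium": {"converged": report.converged, "years": report.years,
                        "residual": report.residual, "tol": report.tol},
        "scenarios": {sid: {"fixed_factors": sorted(s.fixed_factors),
                            "dams": s.dams, "seed": s.seed}
                      for sid, s in scenarios.items()},
        "operator_order": "advection;transformations;n2o_production+rain;reduction;efflux",
    }
    return ProtocolResult(results=results, natural=natural, equilibrium=report,
                          spinup_years=drawn, manifest=manifest)


def attribute(
    results: dict[str, ScenarioResult],
    period: tuple[int, int],
    kinds: Optional[tuple[str, ...]] = None,
) -> pd.DataFrame:
    """Per-factor contributions to the emission change between two decades.

    Factor f's absolute contribution = (decadal change in S1) - (decadal
    change in the run with f fixed); relative contribution = absolute /
    |net S1 change| * 100 (sign preserved, so suppressing factors come out
    negative).  The interaction residual (net change minus the sum of
    contributions) is reported as its own row, and a second normalisation
    over the listed factors only (``relative_over_factors_pct``) is emitted
    alongside.
    """
    if "S1" not in results:
        raise ValueError("attribution requires the all-transient run 'S1'")
    dec_a, dec_b = period

    def change(res: ScenarioResult) -> float:
        dec = res.decadal(kinds)["mean_GgN"]
        if dec_a not in dec.index or dec_b not in dec.index:
            raise ValueError(f"decades {period} not covered by scenario {res.scenario.scenario_id}")
        return float(dec.loc[dec_b] - dec.loc[dec_a])

    net = change(results["S1"])
    rows = []
    contributions = {}
    for sid, res in results.items():
        if sid == "S1":
            continue
        fixed = res.scenario.fixed_factors
        if len(fixed) != 1:
            continue
        factor = next(iter(fixed))
        contributions[factor] = net - change(res)
    total_attr = sum(contributions.values())
    denom = abs(net) if net != 0 else np.nan
    for factor, absolute in contributions.items():
        rows.append({
            "factor": factor,
            "absolute_GgN": absolute,
            "relative_pct": absolute / denom * 100.0 if denom == denom else np.nan,
            "relative_over_factors_pct": (
                absolute / abs(total_attr) * 100.0 if total_attr != 0 else np.nan),
        })
    residual = net - total_attr
    rows.append({
        "factor": "interaction",
        "absolute_GgN": residual,
        "relative_pct": residual / denom * 100.0 if denom == denom else np.nan,
        "relative_over_factors_pct": np.nan,
    })
    df = pd.DataFrame(rows).set_index("factor")
    df.attrs["net_change_GgN"] = net
    df.attrs["period"] = period
    return df


def uncertainty_ensemble(
    tables: NetworkTables,
    fs: ForcingSeries,
    config: Optional[RunConfig] = None,
    load_params: Optional[LoadResponseParams] = None,
    seed: int = 0,
    perturbations: Optional[dict[str, float]] = None,
    center: Optional[ScenarioResult] = None,
    eq_tol: float = 1e-4,
    eq_max_years: int = 500,
    spinup_years: int = 30,
) -> dict[str, ScenarioResult]:
    """Bracketing load-perturbation members: all-low, center, all-high.

    Perturbations are constant multiplicative factors on the terrestrial
    species loads; the two bracketing transients (all species low, all
    species high) are run alongside the unperturbed center.
    """
    pert = DEFAULT_PERTURBATIONS if perturbations is None else perturbations
    config = config or RunConfig()
    lp = load_params or LoadResponseParams()
    network = build_network(tables.cells, tables.reaches, tables.bodies,
                            resolution_deg=config.hydro.resolution_deg)
    sim = Simulator(network, config)
    equilibrium_run(sim, fs, lp, tol=eq_tol, max_years=eq_max_years)
    spinup_run(sim, fs, lp, years=spinup_years, seed=seed)
    branch = sim.snapshot()

    members: dict[str, ScenarioResult] = {}
    variants = {
        "low": {sp: 1.0 - p for sp, p in pert.items()},
        "high": {sp: 1.0 + p for sp, p in pert.items()},
    }
    if center is None:
        variants["center"] = None  # type: ignore[assignment]
    else:
        members["center"] = center
    for name, mult in variants.items():
        sim.restore(branch)
        scenario = Scenario(f"S1-{name}", frozenset(), "on", seed, load_multipliers=mult)
        members[name] = transient_run(sim, fs, scenario, lp)
    return members
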