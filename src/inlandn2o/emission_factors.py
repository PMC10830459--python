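"""Agricultural emission factors, country aggregation, units and skill metrics.

The agricultural emission factor of inland waters is the percentage of
agricultural N additions (synthetic fertilizer + manure) emitted as N2O via
inland waters, computed per region and decade as

    EF_ag = (emissions_all_transient - emissions_ag_fixed) / additions * 100

with negative raw values clamped to zero (undersaturated early decades and
low-agriculture regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EFRecord",
    "ef_ag",
    "ef_table",
    "aggregate_by_country",
    "n_to_co2e",
    "relative_change",
    "ipcc_leaching_discount",
    "validation_metrics",
    "GLOBAL",
]

GLOBAL = "GLOBAL"
N2O_TO_N_MASS_RATIO = 44.0 / 28.0


@dataclass(frozen=True)
class EFRecord:
    """One region x decade emission-factor entry."""

    region: str
    decade: int
    n2o_ag_GgN: float         # agriculture-induced inland-water emissions (S1 - S6)
    additions_GgN: float      # fertilizer + manure N
    ef_pct: float             # clamped emission factor, percent
    clamped: bool = False     # raw EF was negative
    no_agriculture: bool = False  # additions were zero


def ef_ag(
    s1_emissions: float,
    s6_emissions: float,
    additions: float,
    region: str = GLOBAL,
    decade: int = 0,
) -> EFRecord:
    """Emission factor from the all-transient / agriculture-fixed pair.

    All three inputs must refer to the same region and decade, in Gg N yr-1.
    Raw EF = (S1 - S6) / additions * 100; negative values clamp to zero,
    zero additions yield EF 0 with the no-agriculture flag.
    """
    if additions < 0:
        raise ValueError("agricultural N additions cannot be negative")
    diff = s1_emissions - s6_emissions
    if additions == 0:
        return EFRecord(region, decade, diff, 0.0, 0.0,
                        clamped=False, no_agriculture=True)
    raw = diff / additions * 100.0
    if raw < 0:
        return EFRecord(region, decade, diff, additions, 0.0, clamped=True)
    return EFRecord(region, decade, diff, additions, raw)


def ef_table(records: Iterable[EFRecord]) -> pd.DataFrame:
    """Tidy frame of EF records (the ef_by_country.csv content)."""
    return pd.DataFrame([{
        "country_code": r.region, "decade": r.decade, "n2o_ag_GgN": r.n2o_ag_GgN,
        "additions_GgN": r.additions_GgN, "ef_pct": r.ef_pct,
        "flags": ";".join(f for f, on in
                          (("clamped", r.clamped), ("no_agriculture", r.no_agriculture))
                          if on),
    } for r in records])


def aggregate_by_country(
    cell_values: np.ndarray,
    country_codes: np.ndarray,
    include_global: bool = True,
) -> dict[str | int, float]:
    """Sum per-cell values within country codes.

    Code 0 marks unclaimed/ocean cells: excluded from the per-country rows
    but still counted in the GLOBAL total (which sums every cell exactly
    once, so country totals partition the claimed portion).
    """
    cell_values = np.asarray(cell_values, dtype=float)
    country_codes = np.asarray(country_codes)
    if cell_values.shape != country_codes.shape:
        raise ValueError("cell_values and country_codes must align")
    out: dict[str | int, float] = {}
    for code in np.unique(country_codes):
        if code == 0:
            continue
        out[int(code)] = float(cell_values[country_codes == code].sum())
    if include_global:
        out[GLOBAL] = float(cell_values.sum())
    return out


def n_to_co2e(flux_gg_n: float, gwp: float = 273.0) -> float:
    """Convert Gg N2O-N yr-1 to Tg CO2-equivalent yr-1.

    flux * (44/28) * gwp / 1000: the mass ratio converts N2O-N to N2O, the
    warming potential to CO2 equivalents, and 1000 Gg = 1 Tg.
    """
    if flux_gg_n < 0:
        raise ValueError("flux must be >= 0")
    return flux_gg_n * N2O_TO_N_MASS_RATIO * gwp / 1000.0


def relative_change(before: float, after: float) -> float:
    """Percentage change from ``before`` to ``after``."""
    if before == 0:
        raise ValueError("relative change undefined for a zero baseline")
    return (after - before) / before * 100.0


def share_of(part: float, whole: float) -> float:
    """Percentage share of ``part`` in ``whole``."""
    if whole == 0:
        raise ValueError("share undefined for a zero total")
    return part / whole * 100.0


def ipcc_leaching_discount(ef_of_leached_pct: float, leached_fraction: float = 0.24) -> float:
    """Re-express an EF defined per unit leached N as an EF per unit applied N.

    Inventory methodology assumes a fixed fraction of agricultural N
    additions (default 24%) is lost via leaching/runoff; multiplying an
    EF-per-leached-N by that fraction makes it comparable to EF_ag.
    """
    if not 0.0 <= leached_fraction <= 1.0:
        raise ValueError("leached_fraction must lie in [0, 1]")
    return ef_of_leached_pct * leached_fraction


def validation_metrics(observed, simulated) -> dict[str, float]:
    """R-squared of the linear fit and Nash-Sutcliffe efficiency.

    NSE = 1 - sum((o - s)^2) / sum((o - mean(o))^2); 1 is a perfect match,
    0 is no better than predicting the observed mean.
    """
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size < 3:
        raise ValueError("need >= 3 paired points")
    fit = stats.linregress(o, s)
    nse = 1.0 - float(np.sum((o - s) ** 2)) / float(np.sum((o - o.mean()) ** 2))
    return {"r2": float(fit.rvalue**2), "nse": nse}
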