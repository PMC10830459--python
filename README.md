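# inlandn2o

A daily-timestep simulator of nitrogen transport and dissolved nitrous-oxide
(N₂O) dynamics in stream–river–lake–reservoir networks, with a staged
simulation protocol (equilibrium → spin-up → natural-flow → dam-managed
transients), factorial attribution of emission changes to environmental
drivers, and dynamic agricultural emission factors.

## What it does

* **Network** — builds a validated watershed graph from delimited-text tables
  (cells, channel reaches, water bodies). Standing bodies are classified
  *small* (upstream catchment ≤ one grid cell; attached to the subnetwork
  corridor, fed by an intercepted share of hillslope flow) or *large*
  (attached in-line on the main channel).
* **Hydrology** — daily routing with celerity-based reach transfer and
  linear-reservoir (volume / residence-time) outflow for lakes and
  reservoirs; reservoirs are transparent ("pass-through") before their
  construction year or under a natural-flow scenario.
* **Aquatic nitrogen** — advection of NO₃⁻, NH₄⁺, DON and PON plus
  first-order, Q10-scaled decomposition, settling (with a labile-sediment /
  burial split), nitrification, and Michaelis–Menten-limited benthic
  denitrification.
* **N₂O balance** — per-element budget
  `ΔM/Δt = F_a + Y_water + D − R − E` (advection, production, rain
  deposition, reduction to N₂, air–water efflux), closed at machine
  precision every step. Reduction is nitrate-inhibited, so nitrate-depleted
  water bodies can draw N₂O below atmospheric equilibrium and act as sinks
  (negative efflux).
* **Protocol** — equilibrium run, 30-year randomized-climate spin-up, a
  natural-flow transient followed by dam-managed transients 1850–2019, five
  factorial experiments (climate, CO₂, land use, N deposition, agricultural
  N each frozen at first-year values), attribution by differencing, and a
  load-perturbation uncertainty ensemble (±22 / 50 / 37 / 26 % on
  NO₃⁻ / NH₄⁺ / DON / PON).
* **Emission factors** — decadal agricultural emission factors per country
  and globally (clamped at zero), CO₂-equivalent conversion (GWP 273), and
  R² / Nash–Sutcliffe skill metrics.
* **Synthetic data** — generates every input (drainage networks, water-body
  inventories, 1850–2019 forcings, terrestrial N loads) with the response
  structure the analysis assumes: loads rise with warming, cropland
  expansion, deposition and agricultural N, and fall under elevated CO₂;
  agricultural N is manure-only before ~1920 with the synthetic-fertilizer
  share rising to ~45 % by the 1990s.

All mass ledgers (water, nitrogen species, N₂O) are audited: inputs −
outputs − Δstorage closes to ≤1e-9 relative over arbitrary runs.

## Command line

```sh
inlandn2o generate --out world --cells 400 --lakes 8 --reservoirs 4 --seed 7
inlandn2o validate-io world
inlandn2o run-transient  --tables world --out runs/s1
inlandn2o run-factorial  --tables world --out runs/factorial
inlandn2o run-uncertainty --tables world --out runs/uncertainty
inlandn2o attribute --results runs/factorial --period 1850 2010
inlandn2o ef --results runs/factorial --tables world --out ef_by_country.csv
inlandn2o convert --gg-n 583.0        # -> 250.1 Tg CO2e / yr at GWP 273
```

Every run writes a `manifest.yaml` (config, seeds, stage settings); reruns
from the same manifest are bit-identical.

## Conventions

* Cell ids are 0-based row-major; coordinates are cell centres; the grid
  resolution (default 0.5°) sets the cell area used for the size
  classification.
* Units: water m³ (and m³ d⁻¹), nitrogen g N (and g N d⁻¹); aggregated
  outputs in Gg N yr⁻¹; CO₂ equivalents in Tg yr⁻¹.
* `bodies.csv` columns map 1:1 onto HydroLAKES / GRanD attributes;
  `inlandn2o.io.adapt_hydrolakes` / `adapt_grand` convert real extracts
  (with unit conversion) into the native schema.
* All kinetic parameters are documented calibration knobs
  (`inlandn2o.config`); the packaged reference fixture ships a calibrated
  set suited to small domains, recorded in its manifest.
* The package raises glibc's mmap threshold at import to avoid pathological
  allocation costs in containerised environments; set
  `INLANDN2O_NO_MALLOC_TUNING` to disable.

## Layout

```
src/inlandn2o/
  network.py           watershed graph, classification, interception
  hydrology.py         outflow laws, dam modes, routing wrapper
  aquatic_nitrogen.py  species kinetics
  n2o_balance.py       the five-term dissolved-N2O budget
  simulator.py         vectorised daily engine + conservation ledgers
  protocol.py          staged runs, factorial attribution, ensembles
  emission_factors.py  EFs, country aggregation, units, skill metrics
  synthetic_data.py    network/forcing/load generators, reference fixture
  io.py, config.py, cli.py   tables, config, command line
```
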