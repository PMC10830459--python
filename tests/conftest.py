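import numpy as np
import pandas as pd
import pytest

from inlandn2o.config import RunConfig
from inlandn2o.network import build_network
from inlandn2o.simulator import Simulator


def chain_tables(n_cells=2, bodies=(), lats=None):
    """Linear chain 0 -> 1 -> ... -> outlet with simple reach geometry.

    ``bodies`` is a list of dicts overriding the body-row defaults.
    """
    lats = lats if lats is not None else [45.0] * n_cells
    cells = pd.DataFrame({
        "cell_id": range(n_cells),
        "lat": lats,
        "lon": [0.5 * i for i in range(n_cells)],
        "downstream_id": [i + 1 for i in range(n_cells - 1)] + [-1],
        "country_code": [1] * n_cells,
    })
    rows = []
    for i in range(n_cells):
        rows.append({"cell_id": i, "corridor": "subnetwork",
                     "length_m": 60_000.0, "width_m": 10.0, "slope": 1e-3})
        rows.append({"cell_id": i, "corridor": "main",
                     "length_m": 50_000.0, "width_m": 50.0, "slope": 3e-4})
    reaches = pd.DataFrame(rows)
    body_rows = []
    for i, spec in enumerate(bodies):
        row = {"body_id": i, "cell_id": 0, "kind": "lake", "area_m2": 1e7,
               "volume_m3": 1e8, "depth_m": 10.0, "residence_days": 100.0,
               "upstream_m2": 0.0, "built_year": None}
        row.update(spec)
        body_rows.append(row)
    body_cols = ["body_id", "cell_id", "kind", "area_m2", "volume_m3", "depth_m",
                 "residence_days", "upstream_m2", "built_year"]
    bodies_df = pd.DataFrame(body_rows, columns=body_cols)
    return cells, reaches, bodies_df


@pytest.fixture
def chain2():
    """Two-cell chain, no bodies."""
    cells, reaches, bodies = chain_tables(2)
    return build_network(cells, reaches, bodies)


@pytest.fixture
def chain_with_lake():
    """Three-cell chain with one large lake in the middle cell."""
    cells, reaches, bodies = chain_tables(
        3, bodies=[{"cell_id": 1, "upstream_m2": 1e10}])
    return build_network(cells, reaches, bodies)


def make_sim(network, **config_kwargs):
    return Simulator(network, RunConfig(**config_kwargs))


@pytest.fixture
def small_world():
    """36-cell generated world with a few bodies, for protocol-level tests."""
    from inlandn2o.synthetic_data import generate_forcings, generate_network

    tables = generate_network(36, n_lakes=3, n_reservoirs=2, seed=11)
    fs = generate_forcings(tables.cells.lat.to_numpy(), seed=11)
    return tables, fs
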