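import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from inlandn2o.cli import main
from inlandn2o.config import ConfigError, RunConfig
from inlandn2o.io import (
    adapt_grand,
    adapt_hydrolakes,
    read_table,
    read_tables,
    write_gridded_emissions,
)
from inlandn2o.network import SchemaError, build_network
from inlandn2o.synthetic_data import generate_network


def _hash_dir(d: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.glob("*.csv"))}


class TestConfig:
    def test_defaults_round_trip(self, tmp_path):
        cfg = RunConfig()
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_unknown_top_level_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            RunConfig.from_dict({"speling_mistake": 1})

    def test_unknown_nested_key_rejected(self):
        with pytest.raises(ConfigError, match="rates"):
            RunConfig.from_dict({"rates": {"k_dek": 0.1}})

    def test_partial_override(self):
        cfg = RunConfig.from_dict({"rates": {"k_dec": 0.123}, "seed": 9})
        assert cfg.rates.k_dec == 0.123
        assert cfg.rates.k_nit == RunConfig().rates.k_nit
        assert cfg.seed == 9


class TestTables:
    def test_round_trip(self, tmp_path):
        tables = generate_network(16, 2, 1, seed=0)
        tables.write(tmp_path)
        back = read_tables(tmp_path)
        pd.testing.assert_frame_equal(tables.cells, back.cells)
        pd.testing.assert_frame_equal(tables.reaches, back.reaches)
        # bodies: built_year round-trips as float NaN for lakes; compare values
        pd.testing.assert_frame_equal(
            tables.bodies.astype({"built_year": float}), back.bodies)

    def test_missing_column_named(self, tmp_path):
        df = pd.DataFrame({"cell_id": [0], "lat": [45.0]})
        path = tmp_path / "cells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="downstream_id"):
            read_table(path, "cells")

    def test_unknown_table_type(self, tmp_path):
        with pytest.raises(ValueError):
            read_table(tmp_path / "x.csv", "basins")


class TestAdapters:
    def test_hydrolakes_mock_extract(self):
        """5-row HydroLAKES-style attribute extract adapts and validates."""
        mock = pd.DataFrame({
            "Hylak_id": [1, 2, 3, 4, 5],
            "Lake_area": [1.5, 20.0, 3.3, 150.0, 0.8],        # km2
            "Vol_total": [15.0, 300.0, 20.0, 3000.0, 4.0],    # million m3
            "Depth_avg": [10.0, 15.0, 6.2, 20.0, 5.0],
            "Res_time": [120.0, 800.0, 60.0, 1500.0, 30.0],
            "Wshd_area": [50.0, 8000.0, 120.0, 60000.0, 10.0],  # km2
            "Extra_col": ["a", "b", "c", "d", "e"],
        })
        bodies = adapt_hydrolakes(mock, cell_id=0)
        assert list(bodies.body_id) == [1, 2, 3, 4, 5]
        assert bodies.area_m2.iloc[0] == pytest.approx(1.5e6)
        assert bodies.volume_m3.iloc[1] == pytest.approx(3.0e8)
        cells, reaches, _ = __import__("conftest").chain_tables(1)
        net = build_network(cells, reaches, bodies)
        assert len(net.bodies) == 5

    def test_grand_mock_extract(self):
        mock = pd.DataFrame({
            "GRAND_ID": [10], "AREA_SKM": [12.0], "CAP_MCM": [240.0],
            "DEPTH_M": [20.0], "RES_TIME": [400.0], "CATCH_SKM": [900.0],
            "YEAR": [1972],
        })
        bodies = adapt_grand(mock, cell_id=0)
        assert bodies.kind.iloc[0] == "reservoir"
        assert bodies.built_year.iloc[0] == 1972

    def test_missing_extract_column(self):
        with pytest.raises(SchemaError, match="Hylak_id"):
            adapt_hydrolakes(pd.DataFrame({"Lake_area": [1.0]}))


class TestDailyForcingTable:
    def test_round_trip(self, tmp_path):
        from inlandn2o.io import read_daily_forcing, write_daily_forcing

        rng = np.random.default_rng(4)
        runoff = rng.uniform(0, 1e6, size=(10, 3))
        loads = rng.uniform(0, 1e4, size=(10, 3, 4))
        path = tmp_path / "loads.csv"
        write_daily_forcing(path, np.arange(3), runoff, loads)
        cell_ids, r2, l2 = read_daily_forcing(path)
        np.testing.assert_array_equal(cell_ids, np.arange(3))
        np.testing.assert_allclose(r2, runoff)
        np.testing.assert_allclose(l2, loads)

    def test_missing_column(self, tmp_path):
        from inlandn2o.io import read_daily_forcing

        pd.DataFrame({"cell_id": [0], "day": [0]}).to_csv(tmp_path / "bad.csv",
                                                          index=False)
        with pytest.raises(SchemaError, match="runoff_m3_d"):
            read_daily_forcing(tmp_path / "bad.csv")


class TestGriddedOutput:
    def test_netcdf_round_trip(self, tmp_path):
        import xarray as xr

        path = tmp_path / "emis.nc"
        years = np.arange(1850, 1855)
        emis = np.random.default_rng(0).uniform(0, 1e6, size=(5, 4))
        write_gridded_emissions(path, years, np.arange(4), emis)
        ds = xr.open_dataset(path, engine="scipy")
        np.testing.assert_allclose(ds.n2o_efflux.values, emis)
        assert ds.n2o_efflux.attrs["units"] == "g N yr-1"
        ds.close()


class TestCli:
    def test_generate_deterministic_hashes(self, tmp_path):
        runner = CliRunner()
        hashes = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            r = runner.invoke(main, ["generate", "--out", str(out), "--cells", "16",
                                     "--lakes", "2", "--reservoirs", "1", "--seed", "7"])
            assert r.exit_code == 0, r.output
            hashes.append(_hash_dir(out))
        assert hashes[0] == hashes[1]

    def test_convert_paper_value(self):
        r = CliRunner().invoke(main, ["convert", "--gg-n", "583.0"])
        assert r.exit_code == 0
        assert r.output.strip() == "250.1"

    def test_validate_io_ok(self, tmp_path):
        generate_network(16, 2, 1, seed=0).write(tmp_path)
        r = CliRunner().invoke(main, ["validate-io", str(tmp_path)])
        assert r.exit_code == 0
        assert "OK" in r.output

    def test_validate_io_cycle_nonzero_exit(self, tmp_path):
        tables = generate_network(9, 0, 0, seed=0)
        cells = tables.cells.copy()
        # rewire two cells into a 2-cycle
        cells.loc[cells.cell_id == 0, "downstream_id"] = 1
        cells.loc[cells.cell_id == 1, "downstream_id"] = 0
        tables.cells = cells
        tables.write(tmp_path)
        r = CliRunner().invoke(main, ["validate-io", str(tmp_path)])
        assert r.exit_code == 1
        assert "cycle" in r.output.lower()

    def test_run_transient_small_world(self, tmp_path):
        gen = tmp_path / "world"
        out = tmp_path / "out"
        runner = CliRunner()
        r = runner.invoke(main, ["generate", "--out", str(gen), "--cells", "9",
                                 "--lakes", "1", "--reservoirs", "1", "--seed", "3"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "run-transient", "--tables", str(gen), "--out", str(out),
            "--start", "1850", "--end", "1859", "--seed", "3",
            "--eq-tol", "1e-3", "--eq-max-years", "20", "--spinup-years", "2"])
        assert r.exit_code == 0, r.output
        annual = pd.read_csv(out / "S1_annual.csv")
        assert set(annual.columns) == {"year", "kind", "size_class", "country",
                                       "emission_gN"}
        manifest = yaml.safe_load((out / "manifest.yaml").read_text())
        assert manifest["seed"] == 3
        assert "config" in manifest


class TestCliPipeline:
    def test_factorial_attribute_ef_chain(self, tmp_path):
        """End-to-end: generate -> run-factorial -> attribute -> ef."""
        runner = CliRunner()
        gen, out = tmp_path / "world", tmp_path / "runs"
        r = runner.invoke(main, ["generate", "--out", str(gen), "--cells", "9",
                                 "--lakes", "1", "--reservoirs", "1", "--seed", "2"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "run-factorial", "--tables", str(gen), "--out", str(out),
            "--start", "1850", "--end", "1869", "--seed", "2",
            "--eq-tol", "1e-3", "--eq-max-years", "20", "--spinup-years", "2"])
        assert r.exit_code == 0, r.output
        for sid in ("S1", "S2", "S3", "S4", "S5", "S6"):
            assert (out / f"{sid}_annual.csv").exists()
        att = tmp_path / "attribution.csv"
        r = runner.invoke(main, ["attribute", "--results", str(out),
                                 "--period", "1850", "1860", "--out", str(att)])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(att)
        assert set(table.factor) == {"climate", "co2", "landuse", "ndep",
                                     "ag_n", "interaction"}
        ef_out = tmp_path / "ef.csv"
        r = runner.invoke(main, ["ef", "--results", str(out), "--tables", str(gen),
                                 "--seed", "2", "--out", str(ef_out)])
        assert r.exit_code == 0, r.output
        ef = pd.read_csv(ef_out)
        assert (ef.ef_pct >= 0).all()
        assert "GLOBAL" in set(ef.country_code.astype(str))
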