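#!/usr/bin/env python
"""Regenerate the golden-run summary for the packaged reference fixture.

Runs the full staged protocol (equilibrium, spin-up, natural flow, six
factorial scenarios) on the 20x20 fixture and freezes the S1 decadal means
into tests/data/golden_s1.json for regression testing.
"""

import json
import time
from pathlib import Path

from inlandn2o.protocol import run_full_protocol
from inlandn2o.synthetic_data import reference_fixture


def main() -> None:
    fx = reference_fixture()
    t0 = time.time()
    res = run_full_protocol(fx.tables, fx.forcings, fx.config, fx.load_params,
                            seed=fx.seed)
    elapsed = time.time() - t0
    s1 = res.results["S1"]
    golden = {
        "elapsed_s": round(elapsed, 1),
        "equilibrium_years": res.equilibrium.years,
        "spinup_climate_years": res.spinup_years,
        "decadal_total_GgN": {int(k): v for k, v in
                              s1.decadal()["mean_GgN"].items()},
        "decadal_lentic_GgN": {int(k): v for k, v in
                               s1.decadal(kinds=("lake", "reservoir"))["mean_GgN"].items()},
        "decadal_lake_GgN": {int(k): v for k, v in
                             s1.decadal(kinds=("lake",))["mean_GgN"].items()},
    }
    out = Path(__file__).resolve().parent.parent / "tests" / "data" / "golden_s1.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(golden, indent=2))
    print(f"wrote {out} (protocol took {elapsed/60:.1f} min)")


if __name__ == "__main__":
    main()
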