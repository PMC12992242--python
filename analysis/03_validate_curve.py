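#!/usr/bin/env python
"""Validate the 2023 curves against the held-out 2024 synthetic year.

Predicted critical concentrations at each 2024 plot's observed biomass are
compared with that plot's measured concentration; agreement is summarized by
RMSE, nRMSE (with its rating band) and R^2.
"""

import dataclasses
import json
from pathlib import Path

from cndc.cndc_core import PowerCurveFit, predict_nc, validate_predictions
from cndc.trial_data import block_level_samples, read_trial_csv

ROOT = Path(__file__).resolve().parent.parent / "results"
hold = read_trial_csv(ROOT / "data" / "trial_2024.csv")

reports = {}
for part in ("whole_plant", "reproductive"):
    doc = json.loads((ROOT / f"fit_{part}.json").read_text())
    fit = PowerCurveFit(a_c=doc["a_c"], b=doc["b"], r2=doc["r2"],
                        n_points=doc["n_points"], part=part)
    plots = block_level_samples(hold, part=part)
    rep = validate_predictions(
        predict_nc(fit, plots["biomass"].to_numpy()), plots["n_conc"].to_numpy()
    )
    reports[part] = dataclasses.asdict(rep)
    print(f"{part}: RMSE {rep.rmse:.2f} g/kg, nRMSE {rep.nrmse:.2f}% "
          f"({rep.rating}), R2 {rep.r2:.3f}, n = {rep.n}")

(ROOT / "validation.json").write_text(json.dumps(reports, indent=2) + "\n")
print(f"wrote {ROOT / 'validation.json'}")
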