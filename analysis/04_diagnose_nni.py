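#!/usr/bin/env python
"""NNI diagnosis per treatment and stage, and the RY ~ NNI response.

Labels every treatment x stage as deficient / optimal / surplus from the
whole-plant curve, then fits the continuous linear+plateau model of relative
yield on boll-opening NNI over both years.
"""

import dataclasses
import json
from pathlib import Path

from cndc.cndc_core import PowerCurveFit
from cndc.nni import diagnose, fit_linear_plateau, nni_records_to_frame, relative_yield
from cndc.trial_data import aggregate_stage_samples, read_trial_csv, read_yield_csv, yields_to_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
doc = json.loads((ROOT / "fit_whole_plant.json").read_text())
fit = PowerCurveFit(a_c=doc["a_c"], b=doc["b"], r2=doc["r2"],
                    n_points=doc["n_points"], part="whole_plant")

frames, xs, ys = [], [], []
for year in (2023, 2024):
    obs = read_trial_csv(ROOT / "data" / f"trial_{year}.csv")
    samples = aggregate_stage_samples(obs, part="whole_plant")
    records = diagnose(samples, fit)
    frames.append(nni_records_to_frame(records))
    ydf = yields_to_frame(read_yield_csv(ROOT / "data" / f"yields_{year}.csv"))
    ry = relative_yield(dict(ydf.groupby("treatment")["seed_cotton_kg_ha"].mean()))
    for r in records:
        if r.stage == "boll_opening":
            xs.append(r.nni)
            ys.append(ry[r.treatment_id])

import pandas as pd

nni_df = pd.concat(frames)
nni_df.to_csv(ROOT / "nni.csv", index=False)
counts = nni_df.groupby(["treatment_id", "status"]).size().unstack(fill_value=0)
print("status counts per treatment (both years, 4 stages):")
print(counts.to_string())

lp = fit_linear_plateau(xs, ys)
(ROOT / "lp_whole_plant.json").write_text(
    json.dumps(dataclasses.asdict(lp), indent=2) + "\n"
)
print(f"RY = {lp.slope:.4f}*NNI {lp.intercept:+.4f} up to the breakpoint "
      f"NNI = {lp.breakpoint:.3f}; plateau RY = {lp.plateau:.3f} (r2 = {lp.r2:.3f})")
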