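#!/usr/bin/env python
"""Nitrogen-use-efficiency indices, yield stability, and trait correlations.

Computes the seven NUE indices per treatment at boll opening, SI / SYI over
the two simulated years, and the Pearson correlation matrix of NNI, yield and
uptake across treatments.
"""

from pathlib import Path

import pandas as pd

from cndc.agronomy import correlation_matrix, nue_indices, nue_to_frame, stability_indices
from cndc.trial_data import (
    aggregate_stage_samples,
    read_trial_csv,
    read_yield_csv,
    stage_samples_to_frame,
    yields_to_frame,
)

ROOT = Path(__file__).resolve().parent.parent / "results"

ydfs, sdfs = [], []
for year in (2023, 2024):
    ydfs.append(yields_to_frame(read_yield_csv(ROOT / "data" / f"yields_{year}.csv")))
    obs = read_trial_csv(ROOT / "data" / f"trial_{year}.csv")
    sdfs.append(stage_samples_to_frame(aggregate_stage_samples(obs, part="whole_plant")))
ydf = pd.concat(ydfs)
sdf = pd.concat(sdfs)

final = sdf[sdf["stage"] == "boll_opening"]
ymeans = ydf.groupby("treatment").agg(
    n_rate=("n_rate", "first"),
    yield_kg_ha=("seed_cotton_kg_ha", "mean"),
    lint_pct=("lint_pct", "mean"),
)
merged = ymeans.join(
    final.groupby("treatment_id")[["biomass", "n_uptake"]].mean()
).reset_index(names="treatment").rename(
    columns={"biomass": "biomass_t_ha", "n_uptake": "n_uptake_kg_ha"}
)
nue_df = nue_to_frame(nue_indices(merged))
nue_df.to_csv(ROOT / "nue.csv", index=False)
print("NUE indices (per treatment, boll opening):")
print(nue_df.round(3).to_string(index=False))

yearly = ydf.groupby(["treatment", "year"])["seed_cotton_kg_ha"].mean().reset_index()
yearly = yearly.rename(columns={"seed_cotton_kg_ha": "yield_kg_ha"})
stab = pd.DataFrame([r.__dict__ for r in stability_indices(yearly)])
stab.to_csv(ROOT / "stability.csv", index=False)
print("\nstability across years:")
print(stab.round(3).to_string(index=False))

nni_df = pd.read_csv(ROOT / "nni.csv")
nni_final = nni_df[nni_df["stage"] == "boll_opening"].groupby("treatment_id")["nni"].mean()
corr_in = merged.set_index("treatment").join(nni_final.rename("nni"))
r, p = correlation_matrix(corr_in[["n_rate", "yield_kg_ha", "n_uptake_kg_ha", "nni"]])
r.to_csv(ROOT / "correlations.csv")
p.to_csv(ROOT / "correlations_pvalues.csv")
print("\nPearson correlations (treatment level):")
print(r.round(3).to_string())
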