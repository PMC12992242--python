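#!/usr/bin/env python
"""Simulate two years of a randomized-block cotton N-rate trial.

Writes plot-level trial and yield CSVs (plus the generating truth) for the
construction year (2023) and the validation year (2024) under
results/data/.  The two years share the study design — 6 N rates from 0 to
300 kg/ha, 4 blocks, 4 diagnostic stages — and differ only in seed, standing
in for interannual variability.
"""

import json
from pathlib import Path

from cndc.synthetic import SyntheticTrialConfig, generate_trial
from cndc.trial_data import observations_to_frame, yields_to_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# year effects enter through config deltas: 2024 is wetter and higher-yielding,
# with a flatter response (smaller spread between low- and high-N treatments)
YEARS = {
    2023: dict(seed=101, yield_quad=(-0.0083, 7.3172, 1173.9)),
    2024: dict(seed=202, yield_quad=(-0.0070, 6.2, 2400.0)),
}

for year, delta in YEARS.items():
    cfg = SyntheticTrialConfig(year=year, noise_cv=0.05, **delta)
    obs, yields, truth = generate_trial(cfg)
    observations_to_frame(obs).drop(columns="n_uptake_kg_ha").to_csv(
        OUT / f"trial_{year}.csv", index=False
    )
    yields_to_frame(yields).to_csv(OUT / f"yields_{year}.csv", index=False)
    (OUT / f"truth_{year}.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(
        f"{year}: {len(obs)} plot observations, {len(yields)} yield plots "
        f"(true curve {cfg.true_a} * DW^-{cfg.true_b})"
    )
print(f"wrote {OUT}")
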