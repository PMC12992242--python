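#!/usr/bin/env python
"""Yield--N quadratic and the economic optimum N rate.

Fits the quadratic seed-cotton response to N rate over both simulated years,
transforms it into an economic benefit curve at regional prices (seed cotton
5.8, hand harvest 2.6, urea 3.8 yuan/kg at 46.4% N), and reports the optimum
rate and maximum benefit; the published benefit quadratic is evaluated
alongside as a reference.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from cndc.agronomy import (
    Prices,
    build_benefit_curve,
    economic_optimum,
    fit_yield_quadratic,
    vertex,
)
from cndc.trial_data import read_yield_csv, yields_to_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
ydf = pd.concat(
    yields_to_frame(read_yield_csv(ROOT / "data" / f"yields_{y}.csv"))
    for y in (2023, 2024)
)

prices = Prices()
quad = fit_yield_quadratic(ydf["n_rate"], ydf["seed_cotton_kg_ha"])
max_rate, max_yield = vertex(quad)
econ = economic_optimum(build_benefit_curve(quad, prices), prices)
print(f"yield quadratic: Y = {quad[0]:.5f} x^2 + {quad[1]:.4f} x + {quad[2]:.1f}")
print(f"highest-yield rate: {max_rate:.2f} kg N/ha ({max_yield:.0f} kg/ha)")
print(f"economic optimum: {econ.optimal_rate:.2f} kg N/ha, "
      f"max benefit {econ.max_benefit:.2f} yuan/ha")

reference = economic_optimum((-0.02656, 15.22544, 3756.48))
print(f"reference benefit quadratic optimum: {reference.optimal_rate:.2f} kg N/ha, "
      f"{reference.max_benefit:.2f} yuan/ha")

doc = {
    "yield_quad": list(quad),
    "highest_yield_rate_kg_ha": max_rate,
    "benefit_quad": list(econ.quad),
    "optimal_rate_kg_ha": econ.optimal_rate,
    "max_benefit_yuan_ha": econ.max_benefit,
    "prices": dataclasses.asdict(prices),
    "reference_quad_optimum_kg_ha": reference.optimal_rate,
    "reference_quad_max_benefit_yuan_ha": reference.max_benefit,
}
(ROOT / "economics.json").write_text(json.dumps(doc, indent=2) + "\n")
print(f"wrote {ROOT / 'economics.json'}")
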