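"""Seeded generator of randomized-block N-rate trials with a known truth.

The generator emulates the structure that critical-nitrogen-dilution-curve
construction assumes within each sampling stage:

* biomass responds to N supply with a saturating (Michaelis-type) curve, so
  the top rates genuinely plateau and form a clean non-limited group;
* a ground-truth dilution curve ``Nc = true_a * DW^-true_b`` gives the
  critical concentration at any biomass;
* treatments above the agronomic optimum show luxury uptake (concentration
  above the critical curve, no biomass gain), scaled by ``luxury_slope``;
* nitrogen-limited treatments sit below the curve on a stage-specific
  "limited line" that passes through the plateau anchor point
  ``(W_top, Nc(W_top))`` — exactly the geometry the intersection rule relies
  on — with ``deficiency_slope`` setting the fractional depression at the
  zero-N rate.  With both slopes zero, every noiseless concentration lies
  exactly on the true curve.
* replicate (block) values multiply the noiseless value by lognormal noise
  with coefficient of variation ``noise_cv``, keeping all quantities positive.

Because the limited-group geometry is consistent with the construction
method, the full classify -> critical-point -> power-fit pipeline recovers
``(true_a, true_b)`` exactly on noiseless data, which is the basis of the
package's parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trial_data import DEFAULT_STAGES, TrialObservation, YieldRecord
from .cndc_core import PowerCurveFit

#: Stage-wise potential (non-limited) whole-plant biomass, t/ha.  Values span
#: the range over which cotton dilution curves are typically fitted
#: (~2 t/ha at initial flowering to ~14 t/ha at boll opening).
DEFAULT_W_MAX: dict[str, float] = {
    "initial_flowering": 2.2,
    "peak_flowering": 5.5,
    "peak_boll": 10.0,
    "boll_opening": 14.0,
}


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Parameters of one synthetic trial year.

    Defaults mirror a 6-treatment (0-300 kg N/ha), 4-block, 4-stage cotton
    trial.  ``true_a`` / ``true_b`` default to the dilution-curve coefficients
    typical of whole-plant cotton data (a ~ 27 g/kg at 1 t/ha, b ~ 0.28).
    ``yield_quad`` is the seed-cotton response to N rate in kg/ha; the default
    peaks near 440 kg N/ha so that, at regional prices, the economic optimum
    lands near 290 kg N/ha.
    """

    n_rates: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    n_blocks: int = 4
    stages: tuple[str, ...] = DEFAULT_STAGES
    w_max: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_W_MAX))
    true_a: float = 26.936  # g/kg at DW = 1 t/ha
    true_b: float = 0.284  # dilution exponent
    supply_half_saturation: float = 120.0  # kg N/ha
    n0_biomass_fraction: float = 0.45  # biomass at rate 0 relative to potential
    optimal_rate: float = 240.0  # kg N/ha; luxury uptake above, deficiency below
    luxury_slope: float = 0.35  # fractional conc excess per unit relative surplus
    deficiency_slope: float = 0.30  # fractional conc deficit at the zero-N rate
    noise_cv: float = 0.05  # CV of multiplicative lognormal replicate noise
    yield_quad: tuple[float, float, float] = (-0.0083, 7.3172, 1173.9)
    repro_fraction_by_stage: Mapping[str, float] = field(
        default_factory=lambda: {
            "initial_flowering": 0.10,
            "peak_flowering": 0.30,
            "peak_boll": 0.55,
            "boll_opening": 0.70,
        }
    )
    #: reproductive-organ N concentration relative to whole plant
    repro_conc_ratio: float = 1.05
    year: int = 2023
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_a <= 0:
            raise ValueError("true_a must be > 0")
        if not (0 < self.true_b < 1):
            raise ValueError("true_b must lie in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.yield_quad[0] >= 0:
            raise ValueError("yield_quad leading coefficient must be < 0")
        if not (0 < self.n0_biomass_fraction <= 1):
            raise ValueError("n0_biomass_fraction must lie in (0, 1]")
        missing = [s for s in self.stages if s not in self.w_max]
        if missing:
            raise ValueError(f"w_max missing stage(s): {missing}")


def _supply_factor(cfg: SyntheticTrialConfig, n_rate: np.ndarray) -> np.ndarray:
    """Saturating biomass response in (n0_biomass_fraction, 1)."""
    k = cfg.supply_half_saturation
    f0 = cfg.n0_biomass_fraction
    return (f0 * k + np.asarray(n_rate, dtype=float)) / (k + np.asarray(n_rate, dtype=float))


def noiseless_biomass(cfg: SyntheticTrialConfig, stage: str, n_rate) -> np.ndarray:
    return cfg.w_max[stage] * _supply_factor(cfg, np.asarray(n_rate, dtype=float))


def noiseless_concentration(cfg: SyntheticTrialConfig, stage: str, n_rate) -> np.ndarray:
    """Whole-plant N concentration (g/kg) before replicate noise."""
    rates = np.atleast_1d(np.asarray(n_rate, dtype=float))
    w = noiseless_biomass(cfg, stage, rates)
    crit = cfg.true_a * w ** (-cfg.true_b)
    if cfg.luxury_slope == 0 and cfg.deficiency_slope == 0:
        out = crit
    else:
        r_top = max(cfg.n_rates)
        w_top = float(noiseless_biomass(cfg, stage, r_top))
        nc_top = cfg.true_a * w_top ** (-cfg.true_b)
        w0 = float(noiseless_biomass(cfg, stage, 0.0))
        n0 = cfg.true_a * w0 ** (-cfg.true_b) * (1.0 - cfg.deficiency_slope)
        # limited line through (w0, depressed conc) and the plateau anchor
        slope = (nc_top - n0) / (w_top - w0)
        line = n0 + slope * (w - w0)
        surplus = np.maximum(0.0, (rates - cfg.optimal_rate) / cfg.optimal_rate)
        luxury = crit * (1.0 + cfg.luxury_slope * surplus)
        # rates at or below the optimum follow the limited line (the optimum
        # itself sits a hair under critical because its biomass is just short
        # of the plateau); strictly supra-optimal rates show luxury uptake
        out = np.where(rates > cfg.optimal_rate, luxury, line)
    return out if np.ndim(n_rate) else float(out[0])


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    # mean-1 lognormal so noise is unbiased multiplicatively
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_trial(
    cfg: SyntheticTrialConfig,
) -> tuple[list[TrialObservation], list[YieldRecord], dict]:
    """Generate one trial year.

    Returns plot-level observations (vegetative + reproductive organ rows per
    plot), plot-level yield records, and a truth record carrying the
    generating curve and the noiseless treatment-level values.

    The same config (including seed) always produces identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    obs: list[TrialObservation] = []
    truth_rows: list[dict] = []
    blocks = [f"B{i + 1}" for i in range(cfg.n_blocks)]

    for stage in cfg.stages:
        repro_frac = cfg.repro_fraction_by_stage.get(stage, 0.4)
        for rate in cfg.n_rates:
            trt = f"N{int(rate)}"
            w = float(noiseless_biomass(cfg, stage, rate))
            conc = float(noiseless_concentration(cfg, stage, rate))
            # organ split keeping whole-plant totals exact
            w_rep, w_veg = w * repro_frac, w * (1 - repro_frac)
            c_rep = conc * cfg.repro_conc_ratio
            # vegetative conc chosen so the biomass-weighted mean equals conc
            c_veg = (conc * w - c_rep * w_rep) / w_veg
            truth_rows.append(
                {
                    "stage": stage,
                    "treatment": trt,
                    "n_rate": rate,
                    "biomass_t_ha": w,
                    "n_conc_g_kg": conc,
                    "critical_n_conc_g_kg": cfg.true_a * w ** (-cfg.true_b),
                }
            )
            bio_noise = _lognormal_factors(rng, cfg.noise_cv, cfg.n_blocks)
            conc_noise = _lognormal_factors(rng, cfg.noise_cv, cfg.n_blocks)
            for bi, block in enumerate(blocks):
                for part, wp, cp in (
                    ("vegetative", w_veg, c_veg),
                    ("reproductive", w_rep, c_rep),
                ):
                    obs.append(
                        TrialObservation(
                            year=cfg.year,
                            treatment_id=trt,
                            n_rate=rate,
                            block=block,
                            stage=stage,
                            part=part,
                            dry_matter=wp * bio_noise[bi],
                            n_conc=cp * conc_noise[bi],
                        )
                    )

    a2, a1, a0 = cfg.yield_quad
    yields: list[YieldRecord] = []
    for rate in cfg.n_rates:
        trt = f"N{int(rate)}"
        y = a2 * rate**2 + a1 * rate + a0
        # yield components move with rate over agronomically plausible ranges
        lint = 36.0 + 5.0 * rate / 300.0
        weight = 2.7 + 0.9 * rate / 300.0
        density = y / (weight * 10.0)  # bolls/m2 * g/boll * 10 = kg/ha
        y_noise = _lognormal_factors(rng, cfg.noise_cv, cfg.n_blocks)
        for bi, block in enumerate(blocks):
            yields.append(
                YieldRecord(
                    year=cfg.year,
                    treatment_id=trt,
                    n_rate=rate,
                    block=block,
                    seed_cotton_yield=y * y_noise[bi],
                    boll_density=density * y_noise[bi],
                    boll_weight=weight,
                    lint_percentage=lint,
                )
            )

    truth = {
        "true_a": cfg.true_a,
        "true_b": cfg.true_b,
        "year": cfg.year,
        "seed": cfg.seed,
        "noiseless": truth_rows,
        "yield_quad": list(cfg.yield_quad),
    }
    return obs, yields, truth


def true_curve(cfg: SyntheticTrialConfig) -> PowerCurveFit:
    """The generating dilution curve packaged as a fit (r2 = 1 by definition)."""
    return PowerCurveFit(
        a_c=cfg.true_a, b=cfg.true_b, r2=1.0, n_points=0, part="whole_plant"
    )
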