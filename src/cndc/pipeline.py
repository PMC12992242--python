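"""End-to-end orchestration: simulate -> fit -> validate -> diagnose -> metrics.

Every output JSON carries the package version, a config echo and SHA-256
hashes of the input files so runs are auditable; the same config and seed
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .trial_data import (
    DEFAULT_STAGES,
    aggregate_stage_samples,
    block_level_samples,
    observations_to_frame,
    read_trial_csv,
    read_yield_csv,
    stage_samples_to_frame,
    yields_to_frame,
)
from .cndc_core import build_cndc, predict_nc, validate_predictions
from .nni import diagnose, fit_linear_plateau, nni_records_to_frame, relative_yield
from .agronomy import (
    Prices,
    build_benefit_curve,
    economic_optimum,
    fit_yield_quadratic,
    nue_indices,
    nue_to_frame,
    stability_indices,
    vertex,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    trial_csv: Path
    yield_csv: Path
    holdout_csv: Path | None = None
    out_dir: Path = Path("cndc_out")
    part: str = "whole_plant"
    alpha: float = 0.05
    stages: tuple[str, ...] = DEFAULT_STAGES
    nni_tolerance: float = 0.0
    #: use only the first k replicate blocks of the hold-out year for
    #: validation (None = all); published validations sometimes report fewer
    #: replicates than were sown
    validation_blocks: int | None = None
    ry_stage: str = "boll_opening"
    prices: Prices = field(default_factory=Prices)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must lie in (0, 0.5)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _provenance(cfg: RunConfig) -> dict:
    files = {"trial_csv": cfg.trial_csv, "yield_csv": cfg.yield_csv}
    if cfg.holdout_csv:
        files["holdout_csv"] = cfg.holdout_csv
    return {
        "package_version": __version__,
        "input_sha256": {k: _sha256(v) for k, v in files.items()},
        "config": {
            "part": cfg.part,
            "alpha": cfg.alpha,
            "stages": list(cfg.stages),
            "nni_tolerance": cfg.nni_tolerance,
            "ry_stage": cfg.ry_stage,
            "seed": cfg.seed,
        },
    }


def _dump(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full diagnostic workflow; returns the run summary.

    Writes fit.json, validation.json (when a hold-out file is given),
    nni.csv, lp.json, nue.csv, stability.csv (multi-year inputs) and
    economics.json under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    try:
        obs = read_trial_csv(cfg.trial_csv, stages=cfg.stages)
        yrecs = read_yield_csv(cfg.yield_csv)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    # --- curve construction
    try:
        plots = block_level_samples(obs, part=cfg.part)
        fit, points, groupings = build_cndc(plots, alpha=cfg.alpha, part=cfg.part)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    fit_doc = {
        **dataclasses.asdict(fit),
        "critical_points": [dataclasses.asdict(p) for p in points],
        "groupings": [
            {
                "stage": g.stage,
                "limited": sorted(g.limited),
                "non_limited": sorted(g.non_limited),
                "dw_ref": g.dw_ref,
                "flag": g.flag,
            }
            for g in groupings
        ],
        "provenance": prov,
    }
    _dump(fit_doc, out / "fit.json")

    # --- hold-out validation
    validation_doc = None
    if cfg.holdout_csv:
        try:
            hold = read_trial_csv(cfg.holdout_csv, stages=cfg.stages)
            hplots = block_level_samples(hold, part=cfg.part)
            if cfg.validation_blocks is not None:
                keep = sorted(hplots["block"].unique())[: cfg.validation_blocks]
                hplots = hplots[hplots["block"].isin(keep)]
            pred = predict_nc(fit, hplots["biomass"].to_numpy())
            report = validate_predictions(pred, hplots["n_conc"].to_numpy())
        except Exception as exc:
            raise RuntimeError(f"stage 'validate' failed: {exc}") from exc
        validation_doc = {**dataclasses.asdict(report), "provenance": prov}
        _dump(validation_doc, out / "validation.json")

    # --- NNI diagnosis
    try:
        samples = aggregate_stage_samples(obs, part=cfg.part)
        nni_records = diagnose(samples, fit, tolerance=cfg.nni_tolerance)
        nni_df = nni_records_to_frame(nni_records)
        nni_df.to_csv(out / "nni.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'diagnose' failed: {exc}") from exc

    # --- relative yield ~ NNI linear+plateau at the diagnostic stage
    ydf = yields_to_frame(yrecs)
    lp_doc = None
    try:
        trt_yield = ydf.groupby(["year", "treatment"])["seed_cotton_kg_ha"].mean()
        xs, ys = [], []
        for (year, trt), y in trt_yield.items():
            ry = relative_yield(dict(trt_yield.loc[year]))
            rec = nni_df[
                (nni_df["year"] == year)
                & (nni_df["treatment_id"] == trt)
                & (nni_df["stage"] == cfg.ry_stage)
            ]
            if len(rec) == 1:
                xs.append(float(rec["nni"].iloc[0]))
                ys.append(ry[trt])
        lp = fit_linear_plateau(xs, ys)
        lp_doc = {**dataclasses.asdict(lp), "stage": cfg.ry_stage, "provenance": prov}
        _dump(lp_doc, out / "lp.json")
    except ValueError as exc:
        logger.warning("linear+plateau fit skipped: %s", exc)

    # --- NUE indices at the final diagnostic stage
    try:
        sdf = stage_samples_to_frame(samples)
        final = sdf[sdf["stage"] == cfg.stages[-1]]
        ymeans = ydf.groupby("treatment").agg(
            n_rate=("n_rate", "first"),
            yield_kg_ha=("seed_cotton_kg_ha", "mean"),
            lint_pct=("lint_pct", "mean"),
        )
        merged = ymeans.join(
            final.groupby("treatment_id")[["biomass", "n_uptake"]].mean()
        ).reset_index(names="treatment")
        merged = merged.rename(
            columns={"biomass": "biomass_t_ha", "n_uptake": "n_uptake_kg_ha"}
        )
        nue = nue_indices(merged)
        nue_to_frame(nue).to_csv(out / "nue.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'nue' failed: {exc}") from exc

    # --- stability (needs >=2 years)
    stability_doc = None
    yearly = (
        ydf.groupby(["treatment", "year"])["seed_cotton_kg_ha"].mean().reset_index()
    ).rename(columns={"seed_cotton_kg_ha": "yield_kg_ha"})
    if yearly.groupby("treatment")["year"].nunique().min() >= 2:
        reports = stability_indices(yearly)
        pd.DataFrame([r.__dict__ for r in reports]).to_csv(
            out / "stability.csv", index=False
        )
        stability_doc = True

    # --- yield quadratic and economic optimum
    try:
        quad = fit_yield_quadratic(ydf["n_rate"], ydf["seed_cotton_kg_ha"])
        benefit = build_benefit_curve(quad, cfg.prices)
        econ = economic_optimum(benefit, cfg.prices)
        econ_doc = {
            "yield_quad": list(quad),
            "max_yield_rate_kg_ha": vertex(quad)[0] if quad[0] < 0 else None,
            "benefit_quad": list(econ.quad),
            "optimal_rate_kg_ha": econ.optimal_rate,
            "max_benefit_yuan_ha": econ.max_benefit,
            "prices": dataclasses.asdict(cfg.prices),
            "provenance": prov,
        }
        _dump(econ_doc, out / "economics.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'economics' failed: {exc}") from exc

    summary = {
        "fit": {k: fit_doc[k] for k in ("a_c", "b", "r2", "n_points", "part")},
        "validation": validation_doc,
        "n_nni_records": len(nni_df),
        "linear_plateau": lp_doc,
        "economics": {
            "optimal_rate_kg_ha": econ.optimal_rate,
            "max_benefit_yuan_ha": econ.max_benefit,
        },
        "stability_written": bool(stability_doc),
        "out_dir": str(out),
    }
    _dump(summary, out / "run_summary.json")
    return summary
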