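"""Data model and I/O for multi-year, multi-treatment, multi-stage N-rate trials.

Canonical units are fixed throughout the package: biomass in t/ha, nitrogen
concentration in g N per kg dry matter, nitrogen uptake in kg N/ha, yields in
kg/ha.  Readers convert from other units only via explicit schema flags, never
by guessing magnitudes.

Plot-level rows (one per year x treatment x block x stage x organ) are the
unit of entry; block means are computed before treatment summaries so the
randomized-block structure is preserved for the analysis of variance used in
limiting/non-limiting classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Diagnostic stages sampled for N concentration, in phenological order.
DEFAULT_STAGES: tuple[str, ...] = (
    "initial_flowering",
    "peak_flowering",
    "peak_boll",
    "boll_opening",
)

#: Organ classes accepted in plot records. `root` is optional: whole-plant
#: aggregates include it when present so either above-ground or whole-mass
#: conventions can be expressed.
ORGAN_PARTS: tuple[str, ...] = ("vegetative", "reproductive", "root")

TRIAL_COLUMNS = (
    "year",
    "treatment",
    "n_rate",
    "block",
    "stage",
    "part",
    "dry_matter_t_ha",
    "n_conc_g_kg",
)

YIELD_COLUMNS = (
    "year",
    "treatment",
    "n_rate",
    "block",
    "seed_cotton_kg_ha",
    "boll_density_m2",
    "boll_weight_g",
    "lint_pct",
)


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an input table."""


class ValidationError(ValueError):
    """One or more rows violate a field invariant; message cites row numbers."""


@dataclass(frozen=True)
class TrialObservation:
    """One plot-level record: organ biomass and N concentration at one stage."""

    year: int
    treatment_id: str
    n_rate: float  # kg N/ha
    block: str
    stage: str
    part: str  # vegetative | reproductive | root
    dry_matter: float  # t/ha
    n_conc: float  # g N / kg DM


@dataclass(frozen=True)
class StageSample:
    """Treatment-level aggregate for one stage and organ selection.

    ``n_conc`` is the biomass-weighted mean over the selected organ parts,
    then averaged over blocks; ``n_uptake`` is biomass (t/ha) x concentration
    (g/kg), numerically equal to kg N/ha.
    """

    year: int
    treatment_id: str
    n_rate: float
    stage: str
    part: str  # whole_plant | reproductive | vegetative
    biomass: float  # t/ha, mean over blocks
    biomass_sd: float  # t/ha, sample SD over blocks
    n_conc: float  # g/kg
    n_uptake: float  # kg N/ha
    n_blocks: int


@dataclass(frozen=True)
class YieldRecord:
    """Plot-level harvest record."""

    year: int
    treatment_id: str
    n_rate: float
    block: str
    seed_cotton_yield: float  # kg/ha
    boll_density: float  # bolls/m^2
    boll_weight: float  # g
    lint_percentage: float  # % in (0, 100)

    @property
    def lint_yield(self) -> float:
        return self.seed_cotton_yield * self.lint_percentage / 100.0


def population_n_uptake(biomass: float, n_conc: float) -> float:
    """Population N uptake, kg N/ha, from biomass (t/ha) and concentration (g/kg).

    biomass [t/ha] x 1000 [kg/t] x n_conc [g/kg] / 1000 [g/kg -> kg/kg]
    collapses to the plain product: t/ha times g/kg is numerically kg N/ha.
    Accepts scalars or arrays.
    """
    b = np.asarray(biomass, dtype=float)
    c = np.asarray(n_conc, dtype=float)
    if np.any(b < 0) or np.any(c < 0):
        raise ValueError("biomass and n_conc must be non-negative")
    out = b * c
    return float(out) if out.ndim == 0 else out


def _validate_trial_frame(df: pd.DataFrame, stages: Sequence[str]) -> None:
    problems: list[str] = []
    for idx, row in df.iterrows():
        if row["dry_matter_t_ha"] < 0:
            problems.append(f"row {idx}: dry_matter_t_ha={row['dry_matter_t_ha']} < 0")
        if not (0 <= row["n_conc_g_kg"] <= 100):
            problems.append(f"row {idx}: n_conc_g_kg={row['n_conc_g_kg']} outside [0, 100]")
        if row["stage"] not in stages:
            problems.append(f"row {idx}: unknown stage {row['stage']!r} (expected one of {list(stages)})")
        if row["part"] not in ORGAN_PARTS:
            problems.append(f"row {idx}: unknown part {row['part']!r} (expected one of {list(ORGAN_PARTS)})")
        if row["n_rate"] < 0:
            problems.append(f"row {idx}: n_rate={row['n_rate']} < 0")
    if problems:
        raise ValidationError("invalid trial rows:\n" + "\n".join(problems))


def read_trial_csv(
    path,
    schema: Mapping[str, str] | None = None,
    stages: Sequence[str] = DEFAULT_STAGES,
    biomass_unit: str = "t_ha",
    conc_unit: str = "g_kg",
) -> list[TrialObservation]:
    """Read plot-level trial observations from a CSV file.

    Parameters
    ----------
    path
        CSV with header row and columns ``year,treatment,n_rate,block,stage,
        part,dry_matter_t_ha,n_conc_g_kg`` (or names mapped via ``schema``).
    schema
        Optional mapping from canonical column name to the name used in the
        file.
    stages
        Ordered list of admissible stage labels.
    biomass_unit
        ``"t_ha"`` (canonical) or ``"kg_ha"`` (divided by 1000 on read).
    conc_unit
        ``"g_kg"`` (canonical) or ``"percent"`` (x10 on read).

    Raises
    ------
    SchemaError
        if a required column is absent or non-numeric where a number is needed.
    ValidationError
        if any row violates a field invariant; the message cites row numbers.
    """
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("year", "n_rate", "dry_matter_t_ha", "n_conc_g_kg"):
        try:
            raw[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()].tolist()
            raise SchemaError(f"non-numeric values in column {col!r} at row(s) {bad}") from exc
    if biomass_unit == "kg_ha":
        raw["dry_matter_t_ha"] = raw["dry_matter_t_ha"] / 1000.0
    elif biomass_unit != "t_ha":
        raise SchemaError(f"unknown biomass_unit {biomass_unit!r}")
    if conc_unit == "percent":
        raw["n_conc_g_kg"] = raw["n_conc_g_kg"] * 10.0
    elif conc_unit != "g_kg":
        raise SchemaError(f"unknown conc_unit {conc_unit!r}")
    _validate_trial_frame(raw, stages)
    return [
        TrialObservation(
            year=int(r.year),
            treatment_id=str(r.treatment),
            n_rate=float(r.n_rate),
            block=str(r.block),
            stage=str(r.stage),
            part=str(r.part),
            dry_matter=float(r.dry_matter_t_ha),
            n_conc=float(r.n_conc_g_kg),
        )
        for r in raw.itertuples()
    ]


def read_yield_csv(path, schema: Mapping[str, str] | None = None) -> list[YieldRecord]:
    """Read plot-level harvest records from a CSV file."""
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in YIELD_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    problems = []
    for idx, row in raw.iterrows():
        if row["seed_cotton_kg_ha"] < 0 or row["boll_density_m2"] < 0 or row["boll_weight_g"] < 0:
            problems.append(f"row {idx}: negative yield component")
        if not (0 < row["lint_pct"] < 100):
            problems.append(f"row {idx}: lint_pct={row['lint_pct']} outside (0, 100)")
    if problems:
        raise ValidationError("invalid yield rows:\n" + "\n".join(problems))
    return [
        YieldRecord(
            year=int(r.year),
            treatment_id=str(r.treatment),
            n_rate=float(r.n_rate),
            block=str(r.block),
            seed_cotton_yield=float(r.seed_cotton_kg_ha),
            boll_density=float(r.boll_density_m2),
            boll_weight=float(r.boll_weight_g),
            lint_percentage=float(r.lint_pct),
        )
        for r in raw.itertuples()
    ]


def observations_to_frame(obs: Iterable[TrialObservation]) -> pd.DataFrame:
    """Tidy DataFrame with the canonical CSV column names plus uptake."""
    df = pd.DataFrame(
        {
            "year": [o.year for o in obs],
            "treatment": [o.treatment_id for o in obs],
            "n_rate": [o.n_rate for o in obs],
            "block": [o.block for o in obs],
            "stage": [o.stage for o in obs],
            "part": [o.part for o in obs],
            "dry_matter_t_ha": [o.dry_matter for o in obs],
            "n_conc_g_kg": [o.n_conc for o in obs],
        }
    )
    df["n_uptake_kg_ha"] = df["dry_matter_t_ha"] * df["n_conc_g_kg"]
    return df


def yields_to_frame(recs: Iterable[YieldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [r.year for r in recs],
            "treatment": [r.treatment_id for r in recs],
            "n_rate": [r.n_rate for r in recs],
            "block": [r.block for r in recs],
            "seed_cotton_kg_ha": [r.seed_cotton_yield for r in recs],
            "boll_density_m2": [r.boll_density for r in recs],
            "boll_weight_g": [r.boll_weight for r in recs],
            "lint_pct": [r.lint_percentage for r in recs],
        }
    )


def block_level_samples(
    obs: Iterable[TrialObservation], part: str = "whole_plant"
) -> pd.DataFrame:
    """Per-block aggregates for one organ selection.

    For ``part="whole_plant"`` biomass is summed over organ classes and the
    concentration is the biomass-weighted mean; every (year, treatment, block,
    stage) plot must carry both vegetative and reproductive records.

    Returns a DataFrame with columns year, treatment, n_rate, block, stage,
    biomass, n_conc, n_uptake — the unit on which the classification ANOVA runs.
    """
    df = observations_to_frame(obs)
    if part in ("vegetative", "reproductive"):
        sub = df[df["part"] == part].copy()
        if sub.empty:
            raise ValidationError(f"no records with part={part!r}")
        sub = sub.rename(columns={"dry_matter_t_ha": "biomass", "n_conc_g_kg": "n_conc"})
        dup = sub.duplicated(["year", "treatment", "block", "stage"], keep=False)
        if dup.any():
            # collapse duplicate organ rows within a plot by biomass-weighted mean
            sub = (
                sub.groupby(["year", "treatment", "n_rate", "block", "stage"], as_index=False)
                .apply(_weighted_plot, include_groups=False)
                .reset_index(drop=True)
            )
        sub["n_uptake"] = sub["biomass"] * sub["n_conc"]
        return sub[["year", "treatment", "n_rate", "block", "stage", "biomass", "n_conc", "n_uptake"]]
    if part != "whole_plant":
        raise ValueError(f"unknown part {part!r}")
    required = {"vegetative", "reproductive"}
    keys = df.groupby(["year", "treatment", "block", "stage"])["part"].agg(set)
    incomplete = [k for k, s in keys.items() if not required.issubset(s)]
    if incomplete:
        raise ValidationError(
            "whole_plant aggregation needs vegetative and reproductive records; "
            f"incomplete (year, treatment, block, stage) keys: {incomplete}"
        )
    grouped = df.groupby(["year", "treatment", "n_rate", "block", "stage"])
    out = grouped.apply(_weighted_plot, include_groups=False).reset_index()
    out = out.drop(columns=[c for c in out.columns if str(c).startswith("level_")])
    out["n_uptake"] = out["biomass"] * out["n_conc"]
    return out


def _weighted_plot(g: pd.DataFrame) -> pd.Series:
    w = g["dry_matter_t_ha"].to_numpy() if "dry_matter_t_ha" in g else g["biomass"].to_numpy()
    c = g["n_conc_g_kg"].to_numpy() if "n_conc_g_kg" in g else g["n_conc"].to_numpy()
    total = w.sum()
    conc = float(np.average(c, weights=w)) if total > 0 else float(np.mean(c))
    return pd.Series({"biomass": float(total), "n_conc": conc})


def aggregate_stage_samples(
    obs: Iterable[TrialObservation], part: str = "whole_plant"
) -> list[StageSample]:
    """Treatment-level stage samples: block means of plot-level aggregates.

    One StageSample per (year, treatment, stage). Block plots are aggregated
    first (summing organs, biomass-weighting concentrations), then averaged
    across blocks; ``biomass_sd`` is the sample SD over blocks.
    """
    plots = block_level_samples(obs, part=part)
    out: list[StageSample] = []
    for (year, trt, n_rate, stage), g in plots.groupby(["year", "treatment", "n_rate", "stage"]):
        biomass = float(g["biomass"].mean())
        n_conc = float(g["n_conc"].mean())
        out.append(
            StageSample(
                year=int(year),
                treatment_id=str(trt),
                n_rate=float(n_rate),
                stage=str(stage),
                part=part,
                biomass=biomass,
                biomass_sd=float(g["biomass"].std(ddof=1)) if len(g) > 1 else 0.0,
                n_conc=n_conc,
                n_uptake=population_n_uptake(biomass, n_conc),
                n_blocks=int(len(g)),
            )
        )
    return out


def stage_samples_to_frame(samples: Iterable[StageSample]) -> pd.DataFrame:
    rows = [{f.name: getattr(s, f.name) for f in dc_fields(s)} for s in samples]
    return pd.DataFrame(rows)
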