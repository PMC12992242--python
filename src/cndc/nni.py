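"""Nitrogen nutrition index (NNI) diagnosis and relative-yield response.

NNI = Nt / Nc: measured N concentration over the critical concentration
predicted by the dilution curve at the same biomass.  NNI = 1 marks adequate
nutrition, NNI > 1 nitrogen surplus (luxury uptake), NNI < 1 deficiency; an
optional symmetric tolerance widens the "optimal" band around 1.

Relative yield (RY, each treatment's mean yield over the best treatment's
mean within a year) typically responds to end-of-season NNI as a
linear+plateau: linear gain up to a breakpoint NNI, flat beyond it.  The
breakpoint is profiled deterministically (dense SSE grid plus golden-section
refinement), so fits are reproducible and oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .cndc_core import PowerCurveFit, predict_nc
from .trial_data import StageSample


@dataclass(frozen=True)
class NNIRecord:
    year: int
    treatment_id: str
    stage: str
    part: str
    nt: float  # measured, g/kg
    nc: float  # predicted critical, g/kg
    nni: float
    status: str  # deficient | optimal | surplus


@dataclass(frozen=True)
class LinearPlateauFit:
    """y = slope*x + intercept for x <= breakpoint, y = plateau beyond.

    Continuity (plateau = slope*breakpoint + intercept) holds by construction.
    """

    slope: float
    intercept: float
    breakpoint: float
    plateau: float
    r2: float
    n_points: int

    def predict(self, x):
        x = np.asarray(x, float)
        out = np.where(
            x <= self.breakpoint, self.slope * x + self.intercept, self.plateau
        )
        return float(out) if out.ndim == 0 else out


def compute_nni(nt: float, nc: float) -> float:
    """Nitrogen nutrition index: measured over critical concentration."""
    if nc <= 0:
        raise ValueError("critical concentration nc must be > 0")
    if nt < 0:
        raise ValueError("measured concentration nt must be >= 0")
    return nt / nc


def nni_status(nni: float, tolerance: float = 0.0) -> str:
    """deficient / optimal / surplus label with a symmetric band around 1."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if nni < 0:
        raise ValueError("nni must be >= 0")
    if nni > 1.0 + tolerance:
        return "surplus"
    if nni < 1.0 - tolerance:
        return "deficient"
    return "optimal"


def diagnose(
    samples: Iterable[StageSample],
    fit: PowerCurveFit,
    tolerance: float = 0.0,
) -> list[NNIRecord]:
    """NNI per treatment x stage from treatment-mean samples and a fitted curve."""
    out = []
    for s in samples:
        nc = predict_nc(fit, s.biomass)
        nni = compute_nni(s.n_conc, nc)
        out.append(
            NNIRecord(
                year=s.year,
                treatment_id=s.treatment_id,
                stage=s.stage,
                part=s.part,
                nt=s.n_conc,
                nc=nc,
                nni=nni,
                status=nni_status(nni, tolerance),
            )
        )
    return out


def nni_records_to_frame(records: Iterable[NNIRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def relative_yield(yields: Mapping[str, float]) -> dict[str, float]:
    """Treatment-mean yields normalized by the within-year maximum."""
    if not yields:
        raise ValueError("relative_yield needs at least one treatment")
    vals = dict(yields)
    if any(v <= 0 for v in vals.values()):
        raise ValueError("all yields must be > 0")
    ymax = max(vals.values())
    return {k: v / ymax for k, v in vals.items()}


def _lp_sse(x: np.ndarray, y: np.ndarray, c: float) -> tuple[float, float, float]:
    """OLS of y on min(x, c): returns (sse, slope, intercept)."""
    z = np.minimum(x, c)
    if np.ptp(z) == 0:
        mean = float(y.mean())
        return float(np.sum((y - mean) ** 2)), 0.0, mean
    A = np.column_stack([z, np.ones_like(z)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    return float(np.sum((y - pred) ** 2)), float(coef[0]), float(coef[1])


def fit_linear_plateau(x, y, n_grid: int = 200) -> LinearPlateauFit:
    """Continuous linear+plateau least squares with profiled breakpoint.

    The breakpoint is scanned over ``n_grid`` candidates spanning the observed
    x range (for each candidate the two remaining parameters have a closed
    OLS solution on the design [min(x, c), 1]); the best grid cell is then
    refined by bounded scalar minimization.  Breakpoint = max(x) degenerates
    to a pure linear fit, so the piecewise SSE can never exceed the linear
    one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("linear+plateau fit needs at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("no_breakpoint_support: all x identical")
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, n_grid)
    sses = np.array([_lp_sse(x, y, c)[0] for c in grid])
    i = int(np.argmin(sses))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if a < b:
        res = optimize.minimize_scalar(
            lambda c: _lp_sse(x, y, c)[0], bounds=(a, b), method="bounded",
            options={"xatol": 1e-10},
        )
        c_best = float(res.x) if res.fun <= sses[i] else float(grid[i])
    else:
        c_best = float(grid[i])
    sse, slope, intercept = _lp_sse(x, y, c_best)
    plateau = slope * c_best + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return LinearPlateauFit(
        slope=slope,
        intercept=intercept,
        breakpoint=c_best,
        plateau=float(plateau),
        r2=r2,
        n_points=len(x),
    )
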