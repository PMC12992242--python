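"""Critical nitrogen dilution curve construction, fitting and validation.

The construction follows the classic three-step intersection rule applied
per sampling stage:

1. split treatments into a nitrogen-limited and a non-limited group by a
   one-way ANOVA on block-level biomass followed by pairwise comparisons
   against the highest-biomass treatment;
2. regress treatment-mean N concentration on treatment-mean biomass over the
   limited group and evaluate the line at the mean biomass of the non-limited
   group — that intersection is the stage's critical point (DW_ref, Nc);
3. fit the power-law dilution curve Nc = a_c * DW^-b through the per-stage
   critical points by nonlinear least squares on the original scale,
   initialized from log-log OLS.

Validation compares curve predictions at observed biomasses against measured
concentrations with RMSE, nRMSE (% of the observed mean) and R^2 (squared
Pearson correlation), rating model performance by the standard nRMSE bands
(<10% excellent, 10-20% good, 20-30% fair, otherwise poor).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: nRMSE rating bands, upper bounds in percent.
NRMSE_BANDS: tuple[tuple[float, str], ...] = (
    (10.0, "excellent"),
    (20.0, "good"),
    (30.0, "fair"),
    (math.inf, "poor"),
)


@dataclass(frozen=True)
class StageGrouping:
    """Limited / non-limited split of treatments at one stage."""

    stage: str
    limited: frozenset[str]
    non_limited: frozenset[str]
    linear_slope: float | None  # g/kg per t/ha, over limited treatment means
    linear_intercept: float | None  # g/kg
    dw_ref: float | None  # t/ha, mean biomass of the non-limited group
    alpha: float
    flag: str | None = None  # None | no_critical_point | insufficient_limited


@dataclass(frozen=True)
class CriticalPoint:
    stage: str
    dw: float  # t/ha
    nc: float  # g/kg
    n_limited_points: int


@dataclass(frozen=True)
class PowerCurveFit:
    """Fitted dilution curve Nc = a_c * DW^-b."""

    a_c: float  # g/kg at DW = 1 t/ha
    b: float  # dilution exponent
    r2: float  # on the original scale
    n_points: int
    part: str = "whole_plant"
    r2_loglog: float | None = None

    def predict(self, dw) -> np.ndarray:
        return predict_nc(self, dw)


@dataclass(frozen=True)
class ValidationReport:
    rmse: float  # g/kg
    nrmse: float  # % of observed mean
    r2: float
    n: int
    rating: str


def nrmse_rating(nrmse: float) -> str:
    """Rating band for a normalized RMSE given in percent."""
    if nrmse < 0:
        raise ValueError("nrmse must be >= 0")
    for upper, label in NRMSE_BANDS:
        if nrmse < upper:
            return label
    raise AssertionError("unreachable")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value with a deterministic zero-variance branch."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if math.isclose(a.mean(), b.mean(), rel_tol=0, abs_tol=0) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def classify_limiting(
    stage_plots: pd.DataFrame, alpha: float = 0.05, method: str = "welch"
) -> StageGrouping:
    """Split one stage's treatments into limited and non-limited groups.

    Parameters
    ----------
    stage_plots
        Block-level rows for a single stage with columns ``treatment``,
        ``block``, ``biomass`` and ``n_conc`` (as produced by
        :func:`cndc.trial_data.block_level_samples`).
    alpha
        Significance level for the pairwise comparisons.
    method
        ``"welch"`` (default): Welch t-tests of every treatment against the
        highest-biomass treatment.  ``"tukey"``: Tukey HSD over all
        treatments, reading off the comparisons against the top treatment.

    Treatments statistically indistinguishable from the top-biomass treatment
    form the non-limited group (on the biomass plateau); the rest are
    nitrogen-limited.  The grouping also records the OLS line of limited
    treatment-mean concentration on biomass and the mean biomass of the
    non-limited group (``dw_ref``), ready for :func:`critical_point`.
    """
    required = {"treatment", "biomass", "n_conc"}
    if not required.issubset(stage_plots.columns):
        raise ValueError(f"stage_plots must have columns {sorted(required)}")
    stage = str(stage_plots["stage"].iloc[0]) if "stage" in stage_plots else ""
    counts = stage_plots.groupby("treatment").size()
    if len(counts) < 2:
        raise ValueError("classification needs at least 2 treatments")
    if (counts < 2).any():
        raise ValueError(
            "classification needs >=2 replicate blocks per treatment; "
            f"under-replicated: {counts[counts < 2].index.tolist()}"
        )
    means = stage_plots.groupby("treatment")[["biomass", "n_conc"]].mean()
    top = means["biomass"].idxmax()
    by_trt = {t: g["biomass"].to_numpy() for t, g in stage_plots.groupby("treatment")}

    non_limited = {top}
    if method == "tukey":
        order = list(by_trt)
        res = stats.tukey_hsd(*[by_trt[t] for t in order])
        ti = order.index(top)
        for j, t in enumerate(order):
            if t != top and res.pvalue[ti, j] >= alpha:
                non_limited.add(t)
    elif method == "welch":
        for t, vals in by_trt.items():
            if t != top and _welch_p(vals, by_trt[top]) >= alpha:
                non_limited.add(t)
    else:
        raise ValueError(f"unknown method {method!r}")

    limited = set(by_trt) - non_limited
    flag = None
    slope = intercept = None
    dw_ref = float(means.loc[sorted(non_limited), "biomass"].mean())
    if not limited:
        flag = "no_critical_point"
    elif len(limited) < 2:
        flag = "insufficient_limited"
    else:
        lm = means.loc[sorted(limited)]
        slope, intercept, *_ = stats.linregress(lm["biomass"], lm["n_conc"])
        slope, intercept = float(slope), float(intercept)
    if flag:
        logger.info("stage %s: %s (non_limited=%s)", stage, flag, sorted(non_limited))
    else:
        logger.info(
            "stage %s: limited=%s non_limited=%s dw_ref=%.3f",
            stage, sorted(limited), sorted(non_limited), dw_ref,
        )
    return StageGrouping(
        stage=stage,
        limited=frozenset(limited),
        non_limited=frozenset(non_limited),
        linear_slope=slope,
        linear_intercept=intercept,
        dw_ref=dw_ref,
        alpha=alpha,
        flag=flag,
    )


def critical_point(grouping: StageGrouping) -> CriticalPoint:
    """Evaluate the limited-group line at the non-limited mean biomass.

    The critical N concentration at this stage is the ordinate of the
    intersection of the vertical line DW = dw_ref with the OLS line fitted
    over the nitrogen-limited treatments.
    """
    if grouping.flag is not None:
        raise ValueError(f"stage {grouping.stage!r} skipped: {grouping.flag}")
    assert grouping.linear_slope is not None and grouping.linear_intercept is not None
    nc = grouping.linear_intercept + grouping.linear_slope * grouping.dw_ref
    if nc <= 0:
        raise ValueError(
            f"degenerate_critical_point: stage {grouping.stage!r} gives nc={nc:.3f} <= 0"
        )
    return CriticalPoint(
        stage=grouping.stage,
        dw=float(grouping.dw_ref),
        nc=float(nc),
        n_limited_points=len(grouping.limited),
    )


def _loglog_init(dw: np.ndarray, nc: np.ndarray) -> tuple[float, float, float]:
    slope, intercept, r, *_ = stats.linregress(np.log(dw), np.log(nc))
    return math.exp(intercept), -slope, r**2


def fit_power_curve(
    points: Iterable[CriticalPoint] | Sequence[tuple[float, float]],
    part: str = "whole_plant",
) -> PowerCurveFit:
    """Fit Nc = a_c * DW^-b through critical points.

    Nonlinear least squares on the original concentration scale, initialized
    from the log-log OLS solution; R^2 is reported on the original scale
    (log-log R^2 carried alongside).  Deterministic given the inputs.
    """
    pts = list(points)
    if pts and isinstance(pts[0], CriticalPoint):
        dw = np.array([p.dw for p in pts], float)
        nc = np.array([p.nc for p in pts], float)
    else:
        arr = np.asarray(pts, float)
        dw, nc = arr[:, 0], arr[:, 1]
    if len(dw) < 2:
        raise ValueError("power-curve fit needs at least 2 points")
    if np.any(dw <= 0) or np.any(nc <= 0):
        raise ValueError("power-curve fit needs strictly positive dw and nc")
    a0, b0, r2_log = _loglog_init(dw, nc)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * x ** (-b), dw, nc, p0=(a0, b0), maxfev=10000
        )
        a_c, b = float(popt[0]), float(popt[1])
    except RuntimeError as exc:  # non-convergence: fall back to log-log OLS
        logger.warning("power fit did not converge (%s); using log-log OLS", exc)
        a_c, b = a0, b0
    pred = a_c * dw ** (-b)
    ss_res = float(np.sum((nc - pred) ** 2))
    ss_tot = float(np.sum((nc - nc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerCurveFit(
        a_c=a_c, b=b, r2=r2, n_points=len(dw), part=part, r2_loglog=r2_log
    )


def predict_nc(fit: PowerCurveFit, dw):
    """Critical N concentration (g/kg) at biomass dw (t/ha); dw must be > 0."""
    arr = np.asarray(dw, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("dw must be > 0")
    out = fit.a_c * arr ** (-fit.b)
    return float(out) if out.ndim == 0 else out


def validate_predictions(predicted, observed) -> ValidationReport:
    """Agreement statistics between simulated and measured concentrations.

    RMSE = sqrt(mean((P_i - O_i)^2)); nRMSE = RMSE * 100 / mean(O);
    R^2 = squared Pearson correlation of P and O.  The rating is determined
    solely by the nRMSE band.
    """
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D vectors of equal length")
    n = len(p)
    if n < 2:
        raise ValueError("validation needs at least 2 pairs")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    o_mean = float(o.mean())
    if o_mean <= 0:
        raise ValueError("nRMSE undefined: observed mean must be > 0")
    if float(o.std(ddof=0)) == 0 or float(p.std(ddof=0)) == 0:
        raise ValueError("R^2 undefined: zero variance in predicted or observed")
    nrmse = rmse * 100.0 / o_mean
    r2 = float(stats.pearsonr(p, o).statistic ** 2)
    return ValidationReport(rmse=rmse, nrmse=nrmse, r2=r2, n=n, rating=nrmse_rating(nrmse))


def build_cndc(
    plots: pd.DataFrame,
    alpha: float = 0.05,
    part: str = "whole_plant",
    method: str = "welch",
) -> tuple[PowerCurveFit, list[CriticalPoint], list[StageGrouping]]:
    """Run the three-step construction over all stages of one year's plots.

    ``plots`` holds block-level rows (columns treatment, block, stage,
    biomass, n_conc).  Stages without a valid critical point are dropped from
    the fit with a logged warning rather than failing the run.
    """
    groupings: list[StageGrouping] = []
    points: list[CriticalPoint] = []
    for stage, g in plots.groupby("stage", sort=False):
        grouping = classify_limiting(g, alpha=alpha, method=method)
        groupings.append(grouping)
        if grouping.flag is not None:
            logger.warning("stage %s dropped from curve fit: %s", stage, grouping.flag)
            continue
        try:
            points.append(critical_point(grouping))
        except ValueError as exc:
            logger.warning("stage %s dropped from curve fit: %s", stage, exc)
    fit = fit_power_curve(points, part=part)
    return fit, points, groupings
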