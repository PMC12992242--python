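"""Downstream agronomic analytics for N-rate trials.

Covers the seven fertilizer-efficiency indices, multi-year yield stability
and sustainability, the quadratic yield--N-rate response with its economic
optimum, percent-change arithmetic and Pearson correlation matrices.

Index definitions (Y_n, Y_0 seed cotton yield with/without N, F_n the N rate,
NU population N uptake, LP lint fraction, all per hectare):

===========  ==========================  =============================
index        formula                     units
===========  ==========================  =============================
NUE_a        (Y_n - Y_0) / F_n           kg seed cotton per kg N
NUE_i        Y_n * LP / NU               kg lint per kg N uptake
NUE_p        (Y_n - Y_0) / (NU_n-NU_0)   kg seed cotton per kg N uptake
AREN         (NU_n - NU_0) / F_n         fraction of applied N recovered
HI           Y_n / biomass * 100         % (biomass in kg/ha)
NPFP         Y_n / F_n                   kg seed cotton per kg N
===========  ==========================  =============================

Stability over years: SI = Y / SD (mean over replicate-year yields divided by
their sample SD; an SD/Y convention is available by switch) and the
sustainable yield index SYI = (Y - SD) / Y_max with Y_max the best treatment
mean.

Economics: with a fitted yield quadratic Y(x) and prices, the benefit curve
is w(x) = (P_seed - C_harvest) * Y(x) - c_N * x, where c_N is the cost of a
kg of fertilizer N (urea price over its N mass fraction, or a pure-N price
override).  The optimum rate and maximum benefit are the vertex -b/2a and
c - b^2/4a of w.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NUEReport:
    treatment_id: str
    n_rate: float
    nue_a: float | None  # kg seed cotton / kg N; None for the control
    nue_i: float | None  # kg lint / kg N uptake
    nue_p: float | None  # kg seed cotton / kg N uptake
    aren: float | None  # fraction
    hi: float  # %
    npfp: float | None  # kg / kg N
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class StabilityReport:
    treatment_id: str
    mean_yield: float  # kg/ha
    sd_yield: float  # kg/ha
    si: float  # stability index (Y/SD by default)
    syi: float  # sustainable yield index


@dataclass(frozen=True)
class Prices:
    """Regional prices, yuan/kg, and the N mass fraction of urea."""

    seed_cotton_price: float = 5.8
    harvest_cost: float = 2.6
    urea_price: float = 3.8
    urea_n_fraction: float = 0.464
    pure_n_price: float | None = None  # optional override of urea_price/urea_n_fraction

    @property
    def n_cost_per_kg(self) -> float:
        if self.pure_n_price is not None:
            return self.pure_n_price
        return self.urea_price / self.urea_n_fraction

    @property
    def margin_per_kg(self) -> float:
        return self.seed_cotton_price - self.harvest_cost


@dataclass(frozen=True)
class EconomicResult:
    quad: tuple[float, float, float]  # benefit w(x) = a x^2 + b x + c, a < 0
    optimal_rate: float  # kg N/ha, -b/2a
    max_benefit: float  # yuan/ha, c - b^2/4a
    prices: Prices | None = None


def nue_indices(table: pd.DataFrame) -> list[NUEReport]:
    """Fertilizer-efficiency indices per treatment.

    ``table`` carries one row per treatment with columns ``treatment``,
    ``n_rate``, ``yield_kg_ha``, ``lint_pct``, ``biomass_t_ha`` (whole plant
    at harvest/boll opening) and ``n_uptake_kg_ha``.  A control row with
    n_rate = 0 supplies Y_0 and NU_0.  Lint percentage is auto-converted to a
    fraction when given above 1.  Rate-normalized indices are None for the
    control; NUE_p is None (flagged) when the uptake increment vanishes.
    """
    required = {"treatment", "n_rate", "yield_kg_ha", "lint_pct", "biomass_t_ha", "n_uptake_kg_ha"}
    if not required.issubset(table.columns):
        raise ValueError(f"nue_indices needs columns {sorted(required)}")
    controls = table[table["n_rate"] == 0]
    if controls.empty:
        raise ValueError("nue_indices needs a zero-N control treatment")
    y0 = float(controls["yield_kg_ha"].mean())
    nu0 = float(controls["n_uptake_kg_ha"].mean())
    out: list[NUEReport] = []
    for row in table.itertuples():
        yn = float(row.yield_kg_ha)
        fn = float(row.n_rate)
        nu = float(row.n_uptake_kg_ha)
        lp = float(row.lint_pct)
        if lp > 1:
            lp /= 100.0
        biomass_kg = float(row.biomass_t_ha) * 1000.0
        hi = yn / biomass_kg * 100.0
        flags: list[str] = []
        nue_i = yn * lp / nu if nu > 0 else None
        if nu <= 0:
            flags.append("zero_uptake")
        if fn == 0:
            out.append(
                NUEReport(str(row.treatment), fn, None, nue_i, None, None, hi, None, tuple(flags))
            )
            continue
        nue_a = (yn - y0) / fn
        npfp = yn / fn
        aren = (nu - nu0) / fn
        if math.isclose(nu, nu0):
            nue_p = None
            flags.append("undefined_nue_p_equal_uptake")
        else:
            nue_p = (yn - y0) / (nu - nu0)
        out.append(
            NUEReport(str(row.treatment), fn, nue_a, nue_i, nue_p, aren, hi, npfp, tuple(flags))
        )
    return out


def nue_to_frame(reports: Sequence[NUEReport]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in reports])
    return df.drop(columns=["flags"]).assign(flags=[";".join(r.flags) for r in reports])


def stability_indices(
    yearly_yields: pd.DataFrame, convention: str = "Y/SD"
) -> list[StabilityReport]:
    """Yield stability (SI) and sustainability (SYI) per treatment.

    ``yearly_yields`` has one row per treatment x year (columns ``treatment``,
    ``year``, ``yield_kg_ha``); at least two years per treatment.  SD is the
    sample standard deviation across years within treatment; Y_max is the
    largest treatment mean.  With SD = 0 under the Y/SD convention SI is
    reported as +inf with a warning.
    """
    if convention not in ("Y/SD", "SD/Y"):
        raise ValueError("convention must be 'Y/SD' or 'SD/Y'")
    required = {"treatment", "year", "yield_kg_ha"}
    if not required.issubset(yearly_yields.columns):
        raise ValueError(f"stability_indices needs columns {sorted(required)}")
    g = yearly_yields.groupby("treatment")["yield_kg_ha"]
    if (g.size() < 2).any():
        raise ValueError("stability indices need >=2 yield values per treatment")
    means = g.mean()
    sds = g.std(ddof=1)
    y_max = float(means.max())
    out = []
    for trt in means.index:
        y, sd = float(means[trt]), float(sds[trt])
        if sd == 0:
            si = math.inf if convention == "Y/SD" else 0.0
            if convention == "Y/SD":
                logger.warning("treatment %s: SD=0, SI reported as +inf", trt)
        else:
            si = y / sd if convention == "Y/SD" else sd / y
        out.append(
            StabilityReport(
                treatment_id=str(trt),
                mean_yield=y,
                sd_yield=sd,
                si=si,
                syi=(y - sd) / y_max,
            )
        )
    return out


def fit_yield_quadratic(n_rates, yields) -> tuple[float, float, float]:
    """Least-squares quadratic yield response Y(x) = a x^2 + b x + c.

    Needs >=3 distinct rates.  A non-concave fit (a >= 0) is returned with a
    warning — its vertex is a minimum, not a maximum-yield rate.
    """
    x = np.asarray(n_rates, float)
    y = np.asarray(yields, float)
    if len(np.unique(x)) < 3:
        raise ValueError("quadratic fit needs at least 3 distinct N rates")
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:
        logger.warning("yield quadratic is not concave (a=%.4g); vertex is not a maximum", a)
    return float(a), float(b), float(c)


def vertex(quad: tuple[float, float, float]) -> tuple[float, float]:
    """(argmax, max) of a concave quadratic a x^2 + b x + c."""
    a, b, c = quad
    if a >= 0:
        raise ValueError("no maximum: leading coefficient must be < 0")
    x = -b / (2 * a)
    return x, c - b * b / (4 * a)


def build_benefit_curve(
    yield_quad: tuple[float, float, float], prices: Prices
) -> tuple[float, float, float]:
    """Transform a yield quadratic into the economic-benefit quadratic.

    w(x) = (P_seed - C_harvest) * Y(x) - c_N * x, yuan/ha, with c_N the cost
    of one kg of fertilizer N.
    """
    a, b, c = yield_quad
    m = prices.margin_per_kg
    return (m * a, m * b - prices.n_cost_per_kg, m * c)


def economic_optimum(
    benefit_quad: tuple[float, float, float], prices: Prices | None = None
) -> EconomicResult:
    """Economic optimum N rate and maximum benefit from the benefit quadratic."""
    rate, benefit = vertex(benefit_quad)
    return EconomicResult(
        quad=tuple(float(v) for v in benefit_quad),
        optimal_rate=float(rate),
        max_benefit=float(benefit),
        prices=prices,
    )


def percent_change(new: float, ref: float) -> float:
    """100 * (new - ref) / ref."""
    if ref == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new - ref) / ref


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Returns (r, p) DataFrames, symmetric with unit diagonal.  Zero-variance
    columns yield NaN rows/columns (flagged with a warning).
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 3:
        raise ValueError("correlation matrix needs at least 3 rows")
    cols = list(num.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    degenerate = [c for c in cols if num[c].std(ddof=0) == 0]
    if degenerate:
        logger.warning("zero-variance column(s) %s: correlations undefined", degenerate)
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in degenerate or cols[j] in degenerate:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(num[cols[i]], num[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    for i, c in enumerate(cols):
        if c in degenerate:
            r[i, i] = np.nan
            p[i, i] = np.nan
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
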