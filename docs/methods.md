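# Methods

## The problem

In fertilizer trials, plant nitrogen concentration falls as biomass
accumulates ("growth dilution"), so a single concentration threshold cannot
say whether a crop is N-limited.  The critical nitrogen dilution curve (CNDC)

    Nc = a_c * DW^(-b)

gives, for each dry-matter level DW (t/ha), the minimum whole-plant N
concentration Nc (g/kg) that still sustains maximum growth; `a_c` is the
critical concentration at 1 t/ha and `b` the dilution exponent.  The nitrogen
nutrition index NNI = Nt / Nc (measured over critical concentration at the
same biomass) then diagnoses status directly: NNI < 1 deficiency, NNI ≈ 1
adequate, NNI > 1 surplus (luxury uptake).  This package implements the full
workflow for a multi-rate randomized-block cotton trial: curve construction,
hold-out validation, NNI diagnosis, the relative-yield response to NNI, and
the downstream fertilizer-efficiency, stability and economic analytics.

## Curve construction (the intersection rule)

Per sampling stage:

1. **Classification.**  Block-level biomass is compared across treatments.
   The treatment with the largest mean biomass anchors the non-limited group;
   every treatment statistically indistinguishable from it (pairwise Welch
   t-test, default alpha = 0.05; Tukey HSD available) joins that group, all
   others are nitrogen-limited.  With zero replicate variance the test
   degenerates; we then treat exactly equal means as indistinguishable and
   unequal means as distinct, which keeps noiseless synthetic runs
   deterministic.  The published procedure states only that groups are split
   by significance of the biomass response; the choice of Welch tests against
   the top treatment is ours, and is configurable.
2. **Critical point.**  Treatment-mean N concentration is regressed on
   treatment-mean biomass over the limited group (ordinary least squares);
   the critical concentration is the value of that line at the mean biomass
   of the non-limited group.  Stages with an empty limited set
   (`no_critical_point`), fewer than two limited treatments
   (`insufficient_limited`) or a non-positive intersection are dropped from
   the fit with a logged reason rather than failing the run.
3. **Power fit.**  The per-stage critical points are fitted with
   `Nc = a_c * DW^(-b)` by nonlinear least squares on the original
   concentration scale, initialized from the log–log OLS solution (which is
   also the fallback on non-convergence).  R² is reported on the original
   scale, with the log–log R² carried alongside, because reviewers of such
   curves usually quote the former.

## Validation

Hold-out plots (typically a second trial year) supply (biomass, measured
concentration) pairs; the curve predicts a concentration at each observed
biomass.  Agreement uses RMSE, nRMSE = RMSE·100/mean(observed), and the
squared Pearson correlation.  Rating bands follow the convention common in
crop-model evaluation: nRMSE < 10% excellent, 10–20% good, 20–30% fair,
otherwise poor.  All treatments and all diagnostic stages enter the pairing —
not only near-critical ones — matching how such validations are reported.
The number of replicates used for validation is an option
(all blocks by default).

## The synthetic trial generator

No raw data accompany the study this design emulates, so every downstream
stage is tested by parameter recovery on synthetic trials with a known truth.
The generator mimics a 6-treatment (0–300 kg N/ha), 4-block, 4-stage trial:

- **Biomass** per stage and rate is `W_max(stage) * (f0*K + r)/(K + r)` — a
  saturating Michaelis-type response (half-saturation K = 120 kg/ha,
  zero-N fraction f0 = 0.45) so top rates genuinely plateau and form a clean
  non-limited group.  `W_max` spans 2.2–14 t/ha from initial flowering to
  boll opening, the range over which cotton CNDCs are usually fitted.
- **Concentration.**  The generating curve defaults to
  `26.936 * DW^(-0.284)`, coefficients typical of whole-plant cotton data.
  Treatments above the agronomic optimum (240 kg/ha by default) show luxury
  uptake: concentration is the critical value inflated by
  `luxury_slope × relative surplus`.  Treatments at or below the optimum lie
  on a stage-specific *limited line* through the plateau anchor
  `(W_top, Nc(W_top))`, with `deficiency_slope` setting the fractional
  depression at the zero-N rate.  Placing limited treatments on a line
  through the anchor is exactly the geometry the intersection rule assumes,
  which makes the generator self-consistent with the construction method:
  the full pipeline recovers `(a_c, b)` to machine precision on noiseless
  data, so any recovery error observed under noise is attributable to noise,
  not to a modelling mismatch.  When both slopes are zero the line
  construction is skipped and every concentration sits exactly on the curve.
  A corollary worth knowing: the deficiency model is *not* continuous in
  `deficiency_slope` at zero — intermediate rates jump from the chord to the
  curve — a deliberate trade for the two exact regimes above.
- **Replicates** multiply noiseless values by mean-one lognormal noise
  (`noise_cv`, default 5%), keeping concentrations and biomasses positive.
- **Yields** follow a concave quadratic in N rate.  The default
  `(-0.0083, 7.3172, 1173.9)` kg/ha is the response implied by
  back-transforming a published regional benefit quadratic through that
  region's prices, so the synthetic economics land near a realistic optimum
  (~290 kg N/ha).  Boll density is derived from yield and boll weight
  (yield ≈ density × weight × 10); lint percentage rises mildly with rate.
- **Years** differ only through config deltas (seed, yield quadratic); there
  is no weather or phenology process model.

What passing recovery tests does **not** show about real data: the generator
has no year × treatment interaction, no spatial block effects, no measurement
bias, and its limited-group geometry is exactly linear — real trials violate
all of these to some degree, so recovery accuracy here is an upper bound on
what field data would allow.

## NNI diagnosis and the RY ~ NNI response

NNI is computed from treatment-mean concentrations by default (a per-block
option exists via the block-level tables).  Status thresholds sit exactly at
1 with an optional symmetric tolerance band.

Relative yield (RY) is each treatment's mean yield over the best treatment's
mean within the same year — the normalization is ours, flagged here because
the convention is often left implicit in the literature.  The RY response to
end-of-season NNI is fitted as a continuous linear+plateau: for each
candidate breakpoint c the remaining two parameters solve a closed-form OLS
on the design `[min(x, c), 1]`; SSE is profiled over a 200-point grid spanning
the observed NNI range and the best cell is refined by bounded scalar
minimization (xatol 1e-10).  This is deterministic and oracle-checkable,
with no dependence on segmented-regression starting values.  Breakpoint at
max(x) reproduces the pure linear fit, so the piecewise SSE never exceeds the
linear one.

## Agronomic analytics

- **NUE indices** (per treatment, vs the zero-N control): agronomic
  efficiency (Y_n−Y_0)/F_n, internal efficiency Y_n·LP/NU, physiological
  efficiency (Y_n−Y_0)/(NU_n−NU_0), apparent recovery (NU_n−NU_0)/F_n,
  harvest index Y_n/biomass·100 (biomass in kg/ha, exactly as conventionally
  printed even though a dimensionless lint-based index is more common), and
  partial factor productivity Y_n/F_n.  Lint percentage above 1 is
  auto-converted to a fraction.  Rate-normalized indices are undefined for
  the control and returned as None; a vanishing uptake increment flags the
  physiological efficiency rather than dividing by ~0.
- **Stability.**  SI = Y/SD with Y and SD the mean and sample SD of a
  treatment's yearly yields (the SD/Y convention is a switch; source
  formulations are ambiguous between the two, and the narrative reading —
  higher SI = more stable — implies Y/SD).  SYI = (Y − SD)/Y_max with Y_max
  the best treatment mean.  SD is taken within treatment across years; an
  SD "between treatments" reading would make per-treatment indices
  impossible.
- **Economics.**  A concave yield quadratic Y(x) becomes a benefit curve
  w(x) = (P_seed − C_harvest)·Y(x) − c_N·x with c_N the cost of one kg of
  fertilizer N (urea price / 0.464 N fraction by default ≈ 8.19 yuan/kg; a
  pure-N price override exists because both figures circulate).  Optimum rate
  and maximum benefit are the closed-form vertex −b/2a and c − b²/4a.

## Numerical choices and degenerate inputs

- Canonical units everywhere: t/ha, g/kg, kg/ha; readers convert only via
  explicit flags (`biomass_unit="kg_ha"`, `conc_unit="percent"`).
- Block means are computed before treatment means; aggregation is
  permutation-invariant and whole-plant uptake is additive over organs to
  1e-9 relative.
- Zero-variance columns in the correlation matrix produce NaN rows/columns
  with a warning instead of raising.
- Validation raises on zero observed mean (nRMSE undefined) and zero
  variance (R² undefined) instead of returning sentinels.
- All fits are deterministic given their inputs; the only randomness in the
  package lives in the generator and is fully seeded.

## Problem sizes

Recovery checks use the default trial (6 × 4 × 4 × 2 organ records = 192
plot rows per year); the noisy-recovery property summarizes 20 seeded
replicates, a size at which the median relative error is a stable statistic
while the whole suite stays interactive.

## Known limitations

- The classification depends on replicate noise through the pairwise tests:
  with very noisy or very few blocks the non-limited group inflates and
  critical points drift low.
- The linear+plateau fit assumes a single breakpoint; responses with a
  declining (toxicity) arm would need a different model.
- No hierarchical/Bayesian CNDC estimation, boundary-line or
  quantile-regression construction variants, and no remote-sensing (SPAD /
  reflectance) NNI estimation.
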