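# Methods

`forecastmort` implements an analysis chain linking daily temperature and
day-ahead forecast errors to county mortality, and projecting the lives
saved by future forecast improvements under climate-warming scenarios.
Because the source data for such analyses (restricted county mortality
records, archived operational forecasts, gridded weather observations,
climate-model output, expert survey microdata) cannot be redistributed,
the package ships a synthetic-data module with known ground truth, and
every stage is validated by parameter recovery rather than by
replicating published point estimates.

## The mortality model

Daily excess mortality in county *c* on day *d* is modelled as a linear
function of a 13-dimensional basis in realized daily-mean temperature
*T* and the demeaned day-ahead forecast error *e* (forecast minus
realization, so *e* > 0 means the forecast ran warm):

- columns 1–4: *T*, *T*², *T*³, *T*⁴;
- columns 5–7: a natural cubic spline in *e* with two internal and two
  boundary knots (defaults −1.7, −0.4, 0.3, 1.8 °C, or resolved from the
  population-weighted 5/35/65/95-th error percentiles);
- columns 8–13: the spline columns interacted with *T* and *T*².

The spline parameterization is fixed explicitly: N₁(e) = e and, with
d_j(e) = [(e−k_j)³₊ − (e−k₄)³₊]/(k₄−k_j), N_{m+1} = d_m − d₃ for
m = 1, 2. This basis is exactly linear outside the boundary knots, so
effects of extreme errors extrapolate linearly. Four polynomial plus
three spline plus six interaction columns give the 13-column daily
design; monthly sums of the daily basis identify the same coefficients
as the (unobservable) daily regression when effects are additive, which
the test suite verifies exactly on noiseless data.

Mortality is observed as county-month rates (deaths per 100,000), so
the daily basis is summed within county-months and regressed on the
monthly rate with:

- county × calendar-month intercepts (persistent local seasonality),
- county × calendar-month linear trends in a consecutive month index,
- state × year-month intercepts (state-level time shocks),
- an indicator for county-month precipitation above the county's own
  sample median,
- base-year county population weights,
- standard errors clustered at the weather-forecast-office (WFO) level
  with the one-way sandwich and the G/(G−1)·(N−1)/(N−K) small-sample
  factor, where K counts regressors plus absorbed effects.

The fixed effects are absorbed by weighted alternating projections
(each variable is repeatedly projected off the county-season
{intercept, trend} cells and the state-time cells until the sup-norm
change is below 1e−13). Absorbed degrees of freedom are counted
exactly: the intercept sets via the connected-components rule for
two-way fixed effects, plus one per county-season cell with an
identified trend slope, minus one per (state, calendar-month) group
containing a slope column — the month index is constant within
state × year-month cells, so each such group's summed trend column is
spanned by the state-time dummies. On a toy panel the absorbed
estimates and clustered covariance agree with an explicit
dummy-variable oracle to 1e−8 relative, including the dof count.

A heterogeneous variant lets the 13 coefficients vary linearly with
county characteristics — annual mean temperature μᵀ, day-to-day
variability σᵀ (RMS one-day temperature change, i.e. the RMSE of a
persistence forecast), and forecast accuracy RMSE_c — each Winsorized
at population-weighted 5th/95th percentiles before entering, with
predictions clipped to the same bands.

### Minimum mortality temperature (MMT)

The MMT is the argmin over [10, 35] °C of the fitted surface at zero
error, located by a 0.1 °C grid search with local parabolic refinement
and ties broken toward the lower temperature. Under the heterogeneous
model, a county whose fitted curve has no interior minimum gets the
29.5 °C cap. At desk scale the zero-error curve is shallow near its
minimum relative to its pointwise standard error, so a single fit's
MMT is noisy by a few degrees; the acceptance script therefore reports
the median across replicate fits. Recovery of a *planted* quadratic
vertex is exact to within the grid tolerance (0.05 °C).

## Conditional forecast-error model

Three stages, fitted on the synthetic historical sample:

1. **Mean**: weighted least squares of the error on a natural cubic
   spline of temperature (boundary knots −15/35 °C, internal knots every
   5 °C) plus WFO intercepts.
2. **Variance**: a Gamma GLM with log link for squared mean-deviations
   on the same spline, WFO intercepts, and a linear calendar-year trend
   δ. The log link keeps extrapolated variances positive and encodes
   proportional (percentage) accuracy gains per year. IRLS starts from
   a log-linear least-squares fit; exact-zero responses are floored at
   1e−12 to keep the Gamma deviance finite.
3. **Standardized pool**: residuals (e − μ̂)/σ̂ pooled into half-open
   5 °C bins of realized temperature ([lo, lo+5), edges at multiples of
   5, nearest-nonempty-bin fallback at sampling time). Future errors
   resample a standardized draw from the bin of the projected
   temperature and reconstruct e = μ̂ + σ̂·z̃, preserving conditional
   skewness and (partially) kurtosis. Like any bin-resampling scheme,
   extreme-bin kurtosis is under-reproduced when bins are sparse.

Forecast-accuracy scenarios modify only the future: within-sample years
keep δ̂, and from the last sample year forward an adjusted trend δ′
applies. δ′ is calibrated by monotone root finding so that the implied
population-weighted national RMSE over an end-century climate panel —
measured about zero, √(mean(σ̂² + μ̂²)), so conditional bias counts as
inaccuracy — equals the scenario target; the calibration residual is
required to be below 1e−6 °C, and a single-site closed form
δ′ = δ̂ + log(target²/current²)/Δyears is reproduced to 1e−8. The
`constant` scenario pins δ′ = 0; `zero_error` returns identically zero
errors.

## Expert elicitation

Each expert reports a best-case/median/worst-case accuracy triplet
(1st/50th/99th percentiles; for accuracy metrics smaller is better) for
2050 and 2100, anchored by their reported 2020 accuracy, in MSE, RMSE,
or MAE. MSE converts by square root; MAE through an OLS line fitted to
historical office-level (MAE, RMSE) pairs. Changes (accuracy divided by
the 2020 anchor; values above 1 — expected degradation — are valid) are
modelled per expert as a skew-lognormal, concretized as
exp(skew-normal(ξ, ω, α)). On the log scale the three percentile
equations reduce to a single monotone equation in α for the
inner/outer spread ratio, solved by bisection, after which ω and ξ
follow linearly; triplets more asymmetric than any skew-normal can
produce get the nearest-feasible shape (|α| capped at 50) with
residuals recorded. Calibration residuals on feasible triplets are
below 1e−6.

Experts pool into a mixture with equal weights by default, or with
exponential performance weights wᵢ ∝ exp(−λ(yᵢ−y_obs)²), λ = 20, based
on each expert's hindcast 2005→2020 change versus the observed change
(computed with a max-shift to avoid underflow). Scenario targets take
the mixture's 10th (accelerated), 50th (central), and 90th (slowed)
percentiles of 2100 change, scaled by the observed base RMSE. Annual
trajectories fit a constant percentage change to the historical RMSE
series (least squares on log first differences) and rescale the rate so
the path passes through the 2100 target exactly — percentage-change
extrapolation keeps the path strictly positive. Trajectories are
anchored only at 2100; 2050 triplets are fitted but not imposed.

## Projection and lives saved

Climate scenarios copy the reference window's daily temperatures into
the evaluation window year-for-year and add a linear warming ramp that
reaches the scenario delta at the first evaluation year (the no-change
scenario is an exact copy). For external model-based projections, a
bias adjustment subtracts the difference between county quadratic
trends fitted to projected and observed annual means, evaluated at a
common anchor year.

Daily excess rates em(T, e) = f̂(T, e) − f̂(MMT, 0) are multiplied by
base-year population / 100,000 (population held fixed; no demographic
projection), summed to annual deaths, and averaged over the
(configurable, default six-year) evaluation window. Hot-day totals keep
days whose realized projected temperature strictly exceeds 20 °C. Lives
saved by a forecast scenario is the constant-accuracy baseline minus
the scenario, computed from identical climate panels and common random
numbers. 95% CIs re-evaluate both projections at coefficient draws from
a multivariate normal with the clustered covariance (re-searching the
MMT per draw); error-model and elicitation uncertainty are deliberately
not propagated. Under the evolving-response variant, end-century county
characteristics are the observed values times the scenario-implied
ratio of end-century to baseline-period characteristics, clipped to the
in-sample Winsorized bands.

## The synthetic world

The generator produces, deterministically per seed:

- **Counties** partitioned into states and WFOs (each nonempty), with
  heterogeneous climatologies, log-normal base populations, initial
  forecast-error SDs, and AC take-up fractions.
- **Weather** on a 365-day (no-leap) calendar: a seasonal sinusoid
  peaking in late July plus a stationary AR(1) anomaly (φ = 0.7,
  marginal SD per county), and intermittent gamma precipitation. The
  no-leap calendar lets a calendar day shift across years without
  February-29 ambiguity.
- **Forecast errors** with conditional mean 0.3 − 0.02·T (too-warm
  forecasts on cold days, too-cool on hot days), SD proportional to the
  county's base SD with a −2%/yr trend, skew-normal shape (15−T)/5
  (positive skew cold, negative hot, |shape| ≈ 3 at the extremes giving
  moment skewness ≈ 0.6), and a two-point scale mixture on days above
  25 °C (5% of draws inflated 2.5×, variance renormalized) injecting
  excess kurtosis with closed-form moments.
- **Mortality** from a known truth surface: the error effect
  (c₀ + c₂·(max(T,0)/10)²)·e² is least-squares-projected onto the nine
  error-basis columns, and the temperature polynomial is set so the
  zero-error curve is exactly curvature·(T − MMT)² after compensating
  for the spline columns' nonzero values at e = 0 — the planted vertex
  (default 27.8 °C) is exact. Defaults: curvature 4e−4 and error
  coefficients giving daily excess rates of order 0.1–0.3 per 100,000,
  a 75/100,000 monthly baseline, i.i.d. normal county-season effects
  (SD 8), state-time shocks (SD 3), county-season trends (SD 0.01 per
  month index), and observation noise (SD 5). Nuisance components are
  i.i.d. normal because any fixed pattern is absorbed identically; the
  randomness stress-tests the within-estimator. Daily mortality is
  latent — only monthly sums are emitted.
- **Suppression imputation** replaces masked county-month rates by
  population-weighted state-month donor means (erroring when a
  state-month has no donor).
- **Experts** whose reported triplets are *exact* quantiles of known
  skew-lognormal laws, some reporting in MAE (via a known linear
  relation) or MSE, enabling round-trip tests.

What the generator does **not** emulate: spatial correlation of weather
or forecast errors across counties, mortality displacement across
months, non-stationary seasonality, population change, or real
suppression mechanics. Passing recovery tests therefore demonstrates
the correctness of the estimators and plumbing under the model's own
assumptions, not robustness to the full complexity of the source data.

## Verification scale and calibration of checks

The parameter-recovery experiment uses 200 counties × 10 years
(≈730,000 county-days, 24,000 county-months) and 20 replicates. The
cluster count defaults to 58 offices — half the 116 in the emulated
study region — rather than scaling offices down proportionally with
counties: with few clusters the sandwich variance has roughly t_{G−1}
tails and the "all 13 coefficients within 3 SE" event loses calibration
(measured hit rates: 0.83 at G = 10, 0.93 at G = 25, ≈0.97 at G = 50).
With 58 clusters the chain attains ≥95% of replicates with all
coefficients within 3 clustered SEs and ≥90% empirical 95%-CI coverage.

Monte-Carlo tolerances elsewhere: binned error moments at n = 1e5
(means within ±0.02–0.05, SDs within 2–10% depending on the check);
scenario-ordering comparisons across *different* climate panels allow
2% slack because warming shifts days across resampling bins and the
drawn errors differ.

## Numerical choices

- Alternating projections: relative sup-norm tolerance 1e−13, cap 2000
  sweeps; per-column scaling of the normal equations (columns span
  T vs. T⁴ magnitudes) with exact back-transformation.
- Collinearity: regressors whose absorbed norm falls below 1e−8 of
  their pre-absorption norm are reported by name; remaining rank
  deficiency is detected on the correlation-scaled normal matrix.
- Single-cluster designs return point estimates with a warning and no
  covariance.
- Weighted quantiles (knots, Winsorizing) use Hazen plotting positions
  on the positive-weight subsample.
- Mixture quantiles invert the CDF by bracketed bisection (xtol 1e−12);
  brute-force grid inversion in tests uses successively refined grids.
- lowess in the AC diagnostic uses span 2/3 with 3 robustness
  iterations; the AC-residual trim is (2.5, 97.5) percentiles and the
  4 lowest mortality-residual counties are dropped.
- Demeaning levels: county (default), county × month,
  county × month × 5 °C bin, or none; knot percentiles are computed on
  demeaned errors by default.

## Known limitations

- CIs reflect regression-coefficient uncertainty only.
- MMT is weakly identified at desk scale (see above).
- Resampled extreme-bin kurtosis is attenuated.
- The heterogeneity model is linear in characteristics and its
  cross-county contrasts are associational, not causal.
- Error draws are independent across counties given the temperature
  bin; a real error field is spatially correlated, so national
  aggregates here understate projection variance.
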