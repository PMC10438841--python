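# Methods

This note records the modeling choices behind `nitroclim`: what each stage
assumes, which knobs matter, what the synthetic data do and do not emulate,
and where the design was genuinely open.

## 1. The loading model

The response is the natural log of annual total-nitrogen load with Gaussian
errors, so loads are conditionally lognormal and `exp(η)` is the *median*
prediction (the lognormal mean would be `exp(η + σ²/2)`). The linear
predictor is strictly additive: a penalized cubic B-spline smooth for annual
precipitation and linear terms for springtime extreme precipitation, annual
temperature, the two log-surplus terms, three land-use percentages, and tile
drainage. No precipitation × temperature interaction surface is included:
the apparent cross-dependence of *absolute* sensitivities (temperature
sensitivity larger where it is wetter, precipitation sensitivity smaller
where it is warmer) arises purely from the exponential back-transform of an
additive log model, and the test suite asserts exactly that. A tensor
interaction could be added as a new `TermSpec` kind, but nothing in the
synthetic truth requires one.

**Splines and penalty.** Each smooth uses `basis_size` (default 10) cubic
B-splines with interior knots at covariate quantiles — robust to the skewed
precipitation distribution. The wiggliness penalty is a second-order
*divided* difference on the coefficients taken at the Greville abscissae;
with non-uniform knots this (unlike the plain second difference) has the
straight lines of x as its null space, so λ → ∞ collapses a smooth to a
linear fit exactly, and the suite checks that limit. Identifiability uses
the usual sum-to-zero constraint, absorbed by a null-space reparameterization
so the penalty transforms consistently. Outside the training range the basis
is extended linearly (value plus boundary derivative), and predictions there
carry an extrapolation warning.

**Smoothness selection.** λ per smooth minimizes GCV,
`n·RSS/(n − EDF)²`, with EDF the trace of the influence matrix. GCV was
chosen over REML because it is the classical default of the GAM framework
used here and is fully reproducible from the penalized least-squares pieces
already in hand; with n ≈ 9,000 and one smooth the two criteria give
indistinguishable fits. Everything is computed from Gram matrices
(`XᵀX`, `Xᵀy`), so a λ evaluation is a p × p solve (p ≈ 18) and the full
fit takes milliseconds.

**BIC.** `BIC = −2 ln L̂ + ln(n)(EDF + 1)` with σ̂² = RSS/n profiled out;
the `+1` counts the residual-variance scale parameter. EDF rather than raw
parameter count penalizes what the penalty actually lets the model spend.

## 2. Covariate selection

Candidates are grouped into categories (precipitation metrics, extreme
metrics, temperature metrics, surplus terms, land-use terms, drainage), each
with a cap — e.g. at most one extreme-precipitation metric, at most four
land-use terms. The search is exhaustive over all admissible combinations
(the closed-form count `∏ Σ_k C(size,k)` is checked against a brute-force
power-set filter), every candidate is fitted, and models are ranked by BIC.
One model beats another only when ΔBIC > 2; anything within 2 of the winner
is reported as a near-tie. Two open choices were resolved as follows:
every category may contribute zero covariates *except* the surplus category
(`min_allowed = 1`), because a nitrogen-loading model with no nitrogen
source term is physically meaningless; and candidate fits that fail are
logged and skipped rather than aborting the search.

## 3. Sensitivities

Relative sensitivity of loading to covariate x is `100 · d ln(median)/dx`,
evaluated as a central finite difference with step h = 1 unit (1 mm, 1 °C)
so the number reads directly as "% per mm" / "% per °C"; absolute
sensitivity differentiates the median itself. The headline averages weight
each training record equally, each record conditioning the other covariates
at its own values — an empirical-distribution average over the historically
observed covariate space. The reported range is the min–max of the
per-record slopes. Sensitivity *curves* pin the target covariate at its
50th/95th training percentiles and sweep a conditioning covariate, with all
else at training medians.

## 4. Synthetic study population

The generator is the package's study design, not a test fixture. Defaults:

| parameter | default | why |
|---|---|---|
| catchments | 258 | realistic monitoring-network scale |
| years | 1981–2017 (first two consumed by the lag) | realistic record length |
| residual sd σ | 0.5 (log scale) | substantial observation/model noise |
| wet-day threshold | 0.1 mm | SDM convention |
| surplus floor | 1 kg N ha⁻¹ yr⁻¹ | keeps ln(N_surplus) defined |
| saturation scale | 950 mm | near-linear < 1,200 mm, flat > 1,500 mm |
| mean annual precip | 400–1,900 mm across catchments | CONUS-like span |
| mean annual temp | −1 to 23 °C across catchments | matches a −2…24 °C record range |

Daily precipitation is a two-state wet/dry occurrence process with
gamma-distributed wet-day amounts (shape 0.7), modulated by lognormal annual
and spring-specific multipliers so that springtime extremes decorrelate
partially from annual totals (they correlate at ~0.5, enough to make joint
identification non-trivial but not degenerate). Monthly temperature is an
annual-cycle cosine plus interannual and monthly noise. Surplus components
(deposition, fertilizer, fixation, manure, human waste, crop uptake) are
AR(1) (ρ = 0.8) around land-use-dependent means and assembled by the budget
identity; the lagged covariate is ln of the *mean* of the two previous
years' surplus (the sum would differ only by a constant inside the log's
elasticity). Tile drainage is positively tied to the cultivated fraction.

**Calibration.** The generative response's temperature and extreme-precip
slopes are set directly from the target average sensitivities
(−6.4 %/°C → β_T = −0.064; 0.12 %/mm → β_E = 0.0012). The saturating
precipitation amplitude A in `A(1 − e^{−P/s})` is calibrated against the
generated precipitation sample itself: the average relative slope is
`(100A/s)·mean(e^{−P/s})`, solved for A so that it equals 0.17 %/mm for the
population actually drawn. This keeps the calibration exact for every seed
instead of only on average. The reference load level corresponds to a yield
of ~4 kg N ha⁻¹ yr⁻¹ on the median 2,000 km² catchment — roughly 15% export
of a typical ~30 kg N ha⁻¹ yr⁻¹ surplus, leaving the loss term
surplus − yield positive over the whole −2…24 °C range as the Q₁₀
computation requires.

**What the generator does not emulate:** spatial correlation between
catchments, discharge or routing, residual autocorrelation, time-varying
land use, heteroscedastic errors, and measurement error in the covariates.
Passing tests therefore demonstrate that the inference chain is correct and
well-calibrated *under the stated generative assumptions*, not that those
assumptions hold for any particular real monitoring network.

## 5. Ensemble generation and bias correction

GCM-like members re-run the weather generator with a member-specific
multiplicative precipitation bias (lognormal, σ = 0.15) and additive
temperature bias (normal, σ = 1.5 °C), plus scenario trends (three SSP-like
scenarios with 0.15/0.30/0.55 °C per decade and 1–3% wet-day-mean per
decade, jittered per member) ramping over the future segment. The bias-free
twin of each member is retained as ground truth.

Scaled distribution mapping corrects each member against observations over
the 1981–2010 reference: gamma fits to wet-day amounts with wet-day-
frequency adjustment for daily precipitation (multiplicative), per-calendar-
month normal fits with linear detrending for monthly temperature (additive).
The correction maps each segment value through its own fitted CDF to the
observed quantile, scaled (precip) or shifted (temp) by the model-projected
change between the segment and the model reference at that quantile — so
corrected reference-period distributions match observations while projected
relative/absolute quantile changes survive. Precipitation is corrected
whole-series (a per-month option would need longer references to keep the
monthly gamma fits stable); temperature is monthly because the data are
monthly. CDF values are kept strictly inside (0, 1) by a tiny flat clamp:
since every CDF is evaluated under the segment's own fitted distribution,
tail corrections remain bounded (gamma quantile ratios tend to the scale
ratio; normal quantile differences grow only like the sd difference), and a
coarser clamp would visibly distort monthly samples of 30 values. Members
lacking reference coverage are skipped with a logged reason.

## 6. Projection, decomposition, ensemble statistics

Per calendar year: `P_annual` = daily sum, `T_annual` = mean of 12 monthly
values, `P_MAM,p>0.95` = total precipitation of March–May days strictly
exceeding the reference-period 95th percentile of wet days (the full amount
of exceeding days, not the excess above the threshold; empirical quantiles
use linear interpolation of order statistics). Changes are
`100·(future − baseline)/baseline` of 30-year averages of yearly median
predictions, with surplus and land-use covariates pinned at current values.
P-only / T-only effects substitute only the respective covariates; for an
additive log model the single-year decomposition is exactly multiplicative,
and period averaging perturbs it by well under 1% for realistic interannual
variability. The mid-century window defaults to 2030–2059 (configurable).
Ensemble robustness is the fraction of members whose combined change shares
the ensemble median's sign, robust at ≥ 80%; tradeoff classes are
`net-increase` (median combined > 0), `offset` (median P-effect > 0 but
combined ≤ 0), else `compound-decrease` — a partition by construction.
Regional aggregation is load-weighted: summed loads before and after, which
equals weighting watershed changes by baseline load.

## 7. Q₁₀ and Monte-Carlo uncertainty

Nitrogen losses are surplus minus loading expressed as areal yields
(loading divided by catchment area in ha — surplus is areal, so the
difference must be too), evaluated on t ∈ [−2, 24] °C in 0.5 °C steps with
non-temperature covariates at training medians. `Q10(t) = L(t+5)/L(t−5)`
for t ∈ [3, 19]; the headline value weights Q10 by the training temperature
distribution. The default weighting averages Q10 at the observed
temperatures directly (each observation a point mass), which makes the
degenerate cases exact; a histogram-density variant (1 °C bins, trapezoid
quadrature on the 0.5 °C grid) is provided and cross-checked against
fine-grid integration. The uncertainty range is (Q10 at 19 °C, Q10 at 3 °C).

Residual uncertainty propagates by sampling the conditional lognormal:
`draw = median · exp(σ̂ z)`, independent across watersheds, members, years
and repetitions (the single global σ̂² is the Gaussian model's one scale
parameter; there is no residual autocorrelation structure to respect).
Draws are per year and then period-averaged, 1,000 repetitions by default,
streamed year-by-year so memory stays at O(watersheds × members × draws).
Only residual uncertainty is propagated — coefficient uncertainty is out of
scope by design.

## 8. Numerical conventions and degenerate inputs

* Smooths with too few distinct values degrade to linear with a warning.
* Non-positive loads are a domain error (log link); covariate rows failing
  invariants are rejected with row-numbered log entries on read.
* λ search over log₁₀λ ∈ [−6, 9] (bounded scalar minimization; Nelder–Mead
  when several smooths are present).
* BIC ties within 2 are reported, the strict minimum still wins; ranking is
  stable (mergesort with lexicographic tie-break) so selection is invariant
  to candidate ordering.
* Fitted models serialize to JSON text and round-trip to 1e-12.
* All randomness flows from a single integer seed per entry point;
  fixed seed ⇒ byte-identical outputs.

## 9. Problem sizes used by the tests

The default test suite runs the full chain at a 60-catchment scale
(~2,100 records) for unit-level checks and at the full 258-catchment,
~9,000-record scale for the recovery checks; bias-correction contracts use
65-year daily series with 16-member ensembles; selection consistency uses
100 replicates of n = 2,000; Monte-Carlo checks use 1,000 draws on
100 watersheds × 16 members. These sizes keep the suite under a minute of
generator time while leaving estimation error well inside the asserted
tolerances.

## 10. Known limitations

* GCV rather than REML can undersmooth in small samples; irrelevant here at
  n ≈ 9,000 but worth revisiting for small real datasets.
* The additive model cannot represent genuine P × T interactions in the
  mean log response; if real data contain them, the decomposition identity
  becomes approximate rather than exact.
* SDM corrects each variable independently; joint P–T dependence of members
  is not adjusted.
* The Q₁₀ conversion attributes *all* non-exported nitrogen to
  denitrification; it is an upper bound on the denitrification share and is
  sensitive to the assumed export fraction.
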