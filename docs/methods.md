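# Methods

## Exposure: directional temperature variability

TV at lag *l* on date *d* is `T(d−l) − mean(T(d−l−1) … T(d−l−w))` with a
plain equal-weight arithmetic mean and baseline window `w = 7` days
(`w = 3` available as a sensitivity variant). The index day is excluded
from its own baseline. TV at lag *l* on day *d* therefore equals TV at lag
0 on day *d−l*; the implementation computes the lag-0 series once per area
and shifts it. Missing temperature anywhere in a required window
invalidates that (date, lag) value — no imputation. The directional split
is a hinge at 0 °C: `up = max(TV, 0)`, `down = min(TV, 0)`; downward
effects are reported per 1 °C *decrease*, i.e. on `|down|`.

## Design: time-stratified case-crossover

Referents for a case day are all other days in the same calendar
year-month sharing the weekday — 3 in months where that weekday occurs 4
times, 4 where it occurs 5 times. Calendar months (not 28-day blocks)
define the strata. Case–referent separation is then always a positive
multiple of 7 days, so no referent's 7-day baseline window can contain the
case day. Each hospitalization forms its own matched set (recurrent
admissions are separate sets); covariates are time-invariant within a set
and are carried unchanged onto referent rows, where the conditional
likelihood cancels them. Events whose case or referent days lack complete
lag-0–6 exposure are dropped and logged.

## Crossbasis

The exposure dimension uses two unit-slope hinges at the threshold
(default 0 °C); the lag dimension uses a natural cubic spline on lags 0–6
with boundary knots at 0 and 6, an intercept, and two interior knots. The
interior knots follow the usual distributed-lag convention of even spacing
on the log-lag scale; with lag 0 inside the range (log 0 undefined) this is
realised as `L^(k/(K+1))`, k = 1..K — here 6^(1/3) ≈ 1.817 and
6^(2/3) ≈ 3.302. This is a stated convention, and both the knot positions
and the threshold are exposed in `CrossbasisSpec`. The lag basis dimension is
therefore 4 and the crossbasis has 8 columns. Entry (direction, k) of a
day's row is Σ_l b_dir(TV_l)·g_k(l) — exact summation, no scaling. The
spline basis is the truncated-power natural-spline construction
(`1, x, d_k − d_{K−1}`), which spans the same space as any other natural
cubic spline parameterisation; all contrasts use the same basis, so
estimates are invariant to this choice.

## Conditional logistic fit

Log-likelihood Σ_sets [η_case − log Σ_j exp(η_j)] with per-set
max-subtraction; analytic gradient and Hessian; Newton–Raphson from β = 0
with step-halving (up to 30 halvings; a step is accepted if it does not
decrease the log-likelihood by more than 1e−9·(|ℓ|+1), the rounding
resolution of the objective at its own scale). Convergence: gradient
max-norm < 1e−8 (default). Covariance is the inverse observed information
at the optimum; inference is Wald throughout (the likelihood-ratio test
appears only in the exposure-response shape comparison, the one place a
nested-model test is called for). Safeguards: sets with no within-set variation in any
design column are dropped and counted; a column with no within-set
variation anywhere is rejected as non-identifiable by name; a singular
Hessian names the collinear columns via pivoted QR; |β| > 15 flags
separation/divergence as non-convergence rather than returning a silent
answer. Per-set integer weights are accepted so that duplicated sets
(events sharing an area and day with identical design rows) can be
collapsed — an exact computational equivalence used by the large
simulations.

## Effects and effect modification

The lag-*l* contrast for a direction has the lag-basis values g_k(l) on
that direction's 4 columns and zeros elsewhere; unit hinge slopes make the
result per 1 °C. SE by delta method, 95% CI = exp(log-OR ± 1.96·SE),
two-sided normal p. Reporting defaults follow where the associations peak:
upward at lag 0, downward at lag 2 — a summary convention, not an
inferential step. Modifier analyses fit one joint model with the full
8-column crossbasis interacted with the 0/1 indicator (16 exposure
columns); level-specific log-ORs are the main (level 0) and main +
interaction (level 1) contrasts, compared with
z = (β₁ − β₂)/√(SE₁² + SE₂²). Because only the crossbasis is interacted,
the joint likelihood factorises over levels and the interaction model
agrees with two stratified fits (verified numerically in the tests).
Set-constant modifiers (season of the case day, case-day pollutant median
split: low = below the median, ties go high) enter only through
interactions, consistent with the self-matched design. No multiplicity
correction is applied to the per-lag p-values; the type-I-error test
measures the per-test rate.

Subgroup analyses (MI subtype, first vs recurrent, region) refit the model
on the event subset rather than using interactions; the region subsets
partition the cohort. Cumulative (summed-lag) ORs are deliberately not
computed, since they would overlap the exposure's own 7-day baseline.

## Exposure-response shape check

Same-day (lag 0) TV enters as a 3-df natural cubic spline — interior knots
at the 33.3rd/66.7th percentiles of observed TV, boundary knots at min/max,
knots recorded in the output — versus the nested linear term, compared by
LR on 2 df. The basis contains the raw linear column, so nesting is exact
and LR ≥ 0 structurally. The curve is reported as log-OR relative to
TV = 0 with delta-method bands. The single-lag (rather than crossbasis)
formulation is a documented choice for this preliminary diagnostic.

## Sensitivity variants

One knob per run: a day-level holiday indicator; same-day mean temperature
as a natural cubic spline (any non-linear smoother would do; 3 df chosen to
match the shape-check convention and exposed in config); one pollutant at a
time as a same-day linear term (same-day is the assumed lag structure for
pollutant adjusters); or the 3-day baseline window, which recomputes the exposure
itself. Adjusters are day-level and hence identifiable; a set-constant
adjuster is rejected by the fitter with a message, while a globally
constant adjuster (e.g. no holidays in range) carries no information and
is dropped so the refit reduces exactly to the base model. Sets with
missing adjuster values are excluded and logged.

## Synthetic data

The generator is the ground-truth instrument for every statistical test.

* **Climate.** Per region: annual-mean offset + seasonal sinusoid (peak at
  day-of-year 201) + stationary AR(1) anomalies. Defaults were moment-
  matched once to Swedish climate summaries: regional annual means
  3.50/6.58/7.74 °C; amplitude 10.5 °C and anomaly SD 2.4 °C with lag-1
  autocorrelation 0.8, chosen so the overall daily SD is ≈ 7.8 °C and the
  realized upward/downward shift medians fall near +1.4/−1.4 °C (the
  regime the method targets). Realized values for a 15-year run: SD ≈ 8.0,
  medians ≈ +1.44/−1.44.
* **Events.** Day-level thinning of a log-linear intensity: event days are
  drawn with probability ∝ exp(seasonal baseline + day-of-week offsets +
  crossbasis(truth) + optional same-day mean-temperature coupling). A
  self-matched design needs only case days, so no non-case cohort is
  simulated; generation is O(days). The default seasonal baseline
  (winter-peaking, amplitude 0.3 on the log scale) is nuisance structure
  the time-stratified matching must absorb. Covariates (sex, age,
  diabetes, recurrent flag, smoking, subtype) are sampled independently of
  the day — time-invariant covariates cannot confound a self-matched
  design — with prevalences mirroring a 70.6-year, 34.5%-female MI
  population. Configured modifier interactions tilt the day-sampling of
  carrier subgroups only.
* **Truth curves.** A single-lag "spike" of log-ORs is not representable
  by the 4-df lag spline, so recovery simulations would conflate
  estimation error with basis misspecification. `smooth_lag_curve(lag,
  value)` returns the minimum-norm lag curve *inside the spline span*
  pinned to `value` at the focal lag; the study truth pins 0.009 at lag 0
  (upward) and 0.003 at lag 2 (downward), magnitudes on the scale typical
  of reported temperature-variability–MI associations.
* **What is not emulated.** Spatial 1-km structure (one series per
  region), movable-feast holidays, weekday/holiday patterns in incidence
  (neutral defaults), humidity, measurement error in exposure assignment,
  and between-patient frailty. Passing tests therefore validate the
  estimator and design logic under a correctly specified intensity, not
  robustness to these real-data features.

## Problem sizes in the test suite

The recovery simulation uses 100 replicates of 50,000 events over the
15-year three-region climate (duplicated case days collapsed into weighted
sets); the type-I-error simulation uses 500 replicates of 400 events over
a 3-year single-region climate; the LR-calibration uses 200 such
replicates. These sizes give Monte-Carlo standard errors small enough for
the stated bands (e.g. ±0.015 on a coverage estimated from 200 pooled
intervals) while keeping the whole suite around two minutes.

## Known limitations

* Wald inference only; no robust/sandwich variance, no exact conditional
  inference for sparse strata, no penalized lag smoothing.
* One case per matched set (the general multi-case conditional likelihood
  is out of scope).
* Persons moving between areas are not modelled; exposure joins on the
  event's area.
* The evenly-spaced-log knot rule and the 3-df mean-temperature spline are
  documented conventions where the methodology leaves a genuinely free
  choice; both are configurable.
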