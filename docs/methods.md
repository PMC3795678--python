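# Methods

## The problem and the model

Syndromic surveillance of daily respiratory deaths asks, for each
calendar day, whether the observed count is higher than expected. A
single annual threshold (an unconditional upper quantile of the counts)
ignores the strong winter peak of respiratory mortality: mid-winter
days get flagged that are seasonally ordinary, and unusually bad summer
days are missed. `qrsurv` instead models the conditional 90th
percentile of the daily count as a linear function of calendar and
environmental predictors and re-classifies days against that moving
threshold.

The estimator is linear quantile regression. For quantile level
τ ∈ (0, 1) (default 0.9) and predicted quantiles qᵢ = xᵢ'β, the fitted
coefficients minimise the weighted sum of absolute deviations (WSAD,
the check/pinball loss summed over days):

    WSAD(β) = (1 − τ) · Σ_{yᵢ < qᵢ} |yᵢ − qᵢ|  +  τ · Σ_{yᵢ > qᵢ} |yᵢ − qᵢ|.

Four specifications are compared:

* **M1** — intercept only: the unconditional τ-quantile, constant over days.
* **M2** — M1 + cosinor seasonal terms + day-of-week indicators.
* **M3** — M2 + one selected lag (1–7 days) of each weather/air-quality
  covariate.
* **M4** — M2 + a trailing 7-day moving average of each covariate.

Models are fitted on the first half of the series (in-sample,
"prediction") and scored on the second half with frozen coefficients
(out-sample, "forecasting"). Goodness of fit is

    R1 = 1 − WSAD_model / WSAD_M1,

the proportionate reduction in WSAD over the unconditional model,
computed separately per sample. M1's R1 is identically 0; out-sample R1
may be negative and is never clamped.

### Exceedance re-classification

Given the unconditional threshold q_u (one number) and the conditional
per-day threshold q_c(t), each day falls in exactly one of four
categories: typical under both, unusual under both, unusual only under
the unconditional threshold (seasonally ordinary days the flat rule
over-flags), or unusual only under the conditional threshold
(seasonally exceptional days the flat rule misses). Exceedance is
strict (`y > q`); a count exactly on a threshold is typical, consistent
with the check loss assigning zero weight at equality.

## Estimation

Check-loss minimisation is solved exactly as its standard linear
program: residuals split into positive and negative parts with weights
τ and 1 − τ, free coefficients, equality constraints Xβ + u − v = y.
The LP is solved with HiGHS dual simplex (scipy `linprog`,
feasibility/optimality tolerances 1e−9), which returns a basic (vertex)
solution. Flat optima exist — e.g. an intercept-only fit when n·τ is an
integer — and the reported vertex then coincides with the *lower* order
statistic; `unconditional_quantile` implements that convention directly
and agrees with the LP fit. Rank deficiency is detected before solving
by column-pivoted QR (tolerance 1e−10) and reported with the names of
the collinear columns. No coefficient standard errors are produced:
model choice here rests on predictive and forecasting WSAD/R1, not on
inference about individual coefficients.

Counts are integers, which leaves the check loss piecewise-flat in the
intercept; an optional remedy is to **jitter** the response with
additive uniform noise on [−0.1, +0.1] before fitting (seeded,
response only; WSAD/R1 are always reported against the original
counts). Jittering is off by default and, by measurement (test suite),
moves R1 by far less than 0.01 at n = 2500.

## Features

* **Cosinor**: cos/sin pairs of period 365.25 d and 182.625 d in
  t = whole days since a fixed origin. The origin is the first date of
  the *full* dataset, so in- and out-sample features share one phase
  convention.
* **Day-of-week**: six 0/1 indicators against a fixed reference weekday
  (Sunday by default — arbitrary; it moves coefficients, not fits).
* **Lag k**: value k calendar days earlier; the first k days and any
  day whose source value is missing become missing.
* **Moving average**: *trailing* window (current day + previous
  window−1), missing if any window day is missing. A trailing window is
  the only alignment a forecast can use.
* **Complete cases**: per model, every row with a missing response or
  predictor is dropped and counted (`dropped_days`). Row sets therefore
  differ across models — lagged models lose rows — and per-model day
  counts are always reported next to the scores.

Out-sample designs are assembled on the full series and then split at
the cutoff, so an early out-sample day may use covariate values from
late in-sample days for its lags; this is information genuinely
available when forecasting.

## Lag selection

For each covariate, one screening model per candidate lag (1..7) is
fitted in-sample and the lag with the lowest WSAD wins; ties break
toward the smallest lag (parsimony, earlier availability). Two choices
the procedure fixes deliberately:

* all candidate fits for a covariate use the complete-case rows common
  to **all** candidate lags — WSADs on different row sets are not
  comparable;
* the screening model includes the seasonal/temporal base terms by
  default (`base_terms=True`), so a lag is judged on signal beyond
  seasonality. With `base_terms=False` the shared seasonal cycle of
  weather and mortality dominates and the selected lag mostly reflects
  confounding; the flag exists because the screening model's exact
  composition is a genuinely open design point.

## Synthetic data

The generator emulates a single-city NMMAPS-like extract: daily counts
negative binomial with log mean = baseline + annual cosinor +
semiannual cosinor + weekday effect + Σ effectⱼ · z-scored lagged
covariate. Covariates are a 365.25-day sinusoid plus AR(1) noise
(φ = 0.7) with a 7-day burn-in so every output day has lags;
missingness is completely at random, cell-wise, applied to the emitted
table only. Ground truth (the realised per-day log mean and the
complete covariates) is returned in a sidecar so recovery tests never
re-derive it from the series.

Default ("paper-like") conditions: 5114 days from 1987-01-01, designed
mean ≈ 13.85 deaths/day with a winter peak (annual cos amplitude 0.18),
empirical 90th percentile ≈ 20, negative-binomial size 100 (mild
overdispersion, Poisson as the size → ∞ limit), weekday effects ≤ 0.03
on the log scale, covariate effects at the lag pattern of the motivating
analysis (CO, NO₂, O₃, dew point at 1 day; temperature and SO₂ at 3
days), and a 0.5% cell-missingness rate that reproduces a realistic
complete-case loss. Baseline 2.5999 was calibrated once so the designed
mean (average of exp(log μ) over days) is 13.85.

What the generator does **not** emulate: influenza epidemics and heat
waves (no epidemic excess process), serial dependence in counts beyond
what the covariates induce, measurement error in pollutants, holidays,
or missingness that is informative. Passing tests therefore show the
pipeline recovers structure *of this kind*; they do not certify
performance on real mortality data.

## Numerical and design choices

* τ default 0.9 everywhere and configurable; nothing in the code is
  specific to 0.9.
* Tie-break and degenerate-optimum conventions as above (LP vertex,
  lower order statistic).
* Calendar gaps in input CSVs are materialised as all-missing rows (with
  a warning) rather than silently concatenated, keeping lags
  calendar-true.
* The pipeline is single-threaded and fully determined by config +
  seed; the run manifest records the config hash, seed and artifact
  checksums, and two runs with the same config and seed are
  byte-identical.
* Test problem sizes (e.g. 2500-day series, 20–50 replicates for the
  recovery and ordering checks) were chosen as the smallest sizes at
  which the designed effects are comfortably detectable by a power
  probe at design time.

## Known limitations

* Single-lag selection per covariate; no distributed-lag or interaction
  terms, and no spline/Fourier seasonality beyond two cosinor cycles.
* No coefficient uncertainty or multi-quantile (crossing-constrained)
  fitting.
* The R1 comparison across models tolerates slightly different
  complete-case row sets per model (day counts are reported so the
  caveat is visible); an alternative is to force a common row set,
  which the published analysis may or may not have done.
* Exceedance flags are per-day; no run-length or sustained-alarm rules.
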