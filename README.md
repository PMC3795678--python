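# qrsurv

Quantile-regression surveillance of daily respiratory deaths: predict
and forecast *higher-than-expected* daily counts, and tell seasonally
ordinary exceedances apart from genuinely unusual ones.

A fixed annual alarm threshold — the unconditional 90th percentile of
daily deaths — flags many mid-winter days that are ordinary for winter
and misses bad summer days. `qrsurv` instead fits the **conditional**
90th percentile as a linear function of calendar and environmental
predictors by quantile regression, i.e. by minimising the weighted sum
of absolute deviations (check loss)

    WSAD(β) = (1 − τ) Σ_{yᵢ<qᵢ} |yᵢ − qᵢ| + τ Σ_{yᵢ>qᵢ} |yᵢ − qᵢ|,   qᵢ = xᵢ'β,

with τ = 0.9 by default, solved exactly as a linear program. Four
nested specifications are compared:

| model | predictors |
|---|---|
| M1 | intercept (unconditional quantile) |
| M2 | + yearly & half-yearly cosinor, day-of-week |
| M3 | + best single 1–7 day lag per weather/air-quality covariate |
| M4 | + trailing 7-day moving averages instead of lags |

Models are fitted on the first half of the series ("in-sample",
prediction) and scored on the second half with frozen coefficients
("out-sample", forecasting). Fit is summarised by
**R1 = 1 − WSAD_model / WSAD_M1**, the proportionate reduction in check
loss over the unconditional model. Days are then re-classified by
exceedance status under the flat versus the conditional threshold.

The expected input is a daily CSV in the NMMAPS single-city layout
(`date, deaths, tmean, dptp, o3, so2, no2, co`); a synthetic generator
with known ground truth emulates that structure for testing and
demonstration.

## Worked example

```sh
qrsurv simulate --n-days 2920 --seed 11 --out demo.csv
qrsurv evaluate demo.csv --cutoff 1990-12-31
```

prints (lag selection runs on the in-sample half first):

```
selected lags: {'tmean': 1, 'dptp': 4, 'o3': 6, 'so2': 3, 'no2': 5, 'co': 2}
               M1_unconditional  M2_seasonal  M3_seasonal_lags  M4_seasonal_ma
sample metric
in     WSAD              1382.5     1085.800          1027.200         840.000
       R1                   0.0        0.215             0.257           0.392
       days              1453.0     1453.000          1402.000        1155.000
out    WSAD              1330.6     1066.000          1079.500         844.900
       R1                   0.0        0.199             0.189           0.365
       days              1446.0     1446.000          1397.000        1138.000
```

Reading this: the seasonal model (M2) reduces the in-sample check loss
by 21.5% over the flat threshold and still forecasts a 19.9% reduction
out-of-sample. Adding selected lags (M3) helps in-sample but not out —
with this seed's weak designed covariate effects the lags partly fit
noise. The `days` row matters: each model is scored on its own
complete-case days (lags and moving averages lose rows), so WSADs are
comparable across samples within a model, and R1 — a ratio against M1
on the same sample — is the cross-model yardstick.

The same analysis is available as a library:

```python
from qrsurv import (paper_like_config, generate, ModelSpec,
                    select_all_lags, evaluate_models)
from qrsurv.selection import lag_map

series, truth = generate(paper_like_config(seed=11, n_days=2920))
lags = lag_map(select_all_lags(series, origin=series.dates[0]))
specs = [ModelSpec.m1(), ModelSpec.m2(), ModelSpec.m3(lags), ModelSpec.m4()]
table = evaluate_models(series, specs, tau=0.9, cutoff="1990-12-31")
print(table.to_frame())
print(table.fits["M2_seasonal"].summary())
```

`ModelSpec`/`assemble_design` build design matrices, `QuantileModel(…).fit()`
returns a results object with named coefficients, the training WSAD,
quantile-balance diagnostics, `predict()` and `summary()`; and
`flag_exceedance` classifies each day as `typical_both`,
`unusual_both`, `unusual_uncond_only` (flagged by the flat threshold
but seasonally ordinary) or `unusual_cond_only` (missed by the flat
threshold but seasonally exceptional). `qrsurv run --config run.yaml`
executes the whole pipeline reproducibly and writes the comparison
table, lag map, fit files, exceedance report and a checksummed
manifest.

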