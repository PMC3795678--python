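"""Per-covariate lag selection by check-loss screening.

For each weather / air-quality covariate, a screening quantile model is
fitted once per candidate lag (1..7 days by default) and the lag with
the lowest weighted sum of absolute deviations wins.  All candidate
fits for one covariate use the identical row set — the complete-case
rows common to *all* candidate lags — because WSAD values computed on
different observations are not comparable.  Ties break toward the
smallest lag (parsimony; earlier availability when forecasting).

By default the screening model contains the seasonal/temporal base
terms (cosinor + day-of-week) alongside the single lagged covariate, so
a lag is judged on signal beyond seasonality; set ``base_terms=False``
to screen with intercept + lag only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import make_cosinor, make_dow_dummies, make_lag
from .quantile import QuantileModel
from .series import COVARIATES, DailySeries


class SelectionError(ValueError):
    """Raised when lag selection cannot be carried out."""


@dataclass(frozen=True)
class LagSelectionResult:
    """Outcome of screening one covariate across candidate lags."""

    covariate: str
    wsad_by_lag: dict[int, float]
    selected_lag: int
    n_rows: int  # common complete-case rows used by every candidate fit

    def __post_init__(self) -> None:
        if self.selected_lag not in self.wsad_by_lag:
            raise SelectionError("selected_lag must be a candidate lag")
        best = min(self.wsad_by_lag.values())
        if self.wsad_by_lag[self.selected_lag] > best + 1e-12:
            raise SelectionError("selected_lag does not attain the minimum WSAD")


def select_lag(
    series: DailySeries,
    covariate: str,
    tau: float = 0.9,
    candidate_lags=range(1, 8),
    base_terms: bool = True,
    origin=None,
    dow_reference: str = "Sun",
) -> LagSelectionResult:
    """Choose the best single lag for one covariate.

    Fits one screening model per candidate lag on the rows where the
    response, the base terms and *every* candidate's lagged value are
    all present, records each fit's WSAD, and returns the argmin (ties
    to the smallest lag).
    """
    if covariate not in COVARIATES:
        raise SelectionError(f"unknown covariate {covariate!r}; expected one of {COVARIATES}")
    lags = sorted(int(k) for k in candidate_lags)
    if not lags:
        raise SelectionError("candidate_lags must be non-empty")
    if any(k < 1 for k in lags):
        raise SelectionError(f"candidate lags must be >= 1, got {lags}")

    frame = series.frame
    if origin is None:
        origin = frame.index[0]
    lagged = {k: make_lag(frame[covariate], k) for k in lags}

    base = pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
    if base_terms:
        base = pd.concat(
            [base, make_cosinor(frame.index, origin), make_dow_dummies(frame.index, dow_reference)],
            axis=1,
        )

    keep = frame["deaths"].notna()
    for k in lags:
        keep &= lagged[k].notna()
    if not keep.any():
        raise SelectionError(f"covariate {covariate!r} has no complete rows after lagging")
    y = frame.loc[keep, "deaths"].to_numpy(dtype=float)

    wsad_by_lag: dict[int, float] = {}
    for k in lags:
        X = base.loc[keep].copy()
        X[f"{covariate}_lag{k}"] = lagged[k].loc[keep]
        res = QuantileModel(y, X, tau=tau).fit()
        wsad_by_lag[k] = res.train_wsad

    best = min(wsad_by_lag.values())
    selected = min(k for k, v in wsad_by_lag.items() if v <= best + 1e-12)
    return LagSelectionResult(
        covariate=covariate,
        wsad_by_lag=wsad_by_lag,
        selected_lag=selected,
        n_rows=int(keep.sum()),
    )


def select_all_lags(
    series: DailySeries,
    covariates=COVARIATES,
    tau: float = 0.9,
    candidate_lags=range(1, 8),
    base_terms: bool = True,
    origin=None,
    dow_reference: str = "Sun",
) -> list[LagSelectionResult]:
    """Run :func:`select_lag` independently per covariate, preserving order."""
    covariates = list(covariates)
    if not covariates:
        raise SelectionError("covariates must be non-empty")
    results = []
    for cov in covariates:
        try:
            results.append(
                select_lag(
                    series,
                    cov,
                    tau=tau,
                    candidate_lags=candidate_lags,
                    base_terms=base_terms,
                    origin=origin,
                    dow_reference=dow_reference,
                )
            )
        except SelectionError:
            raise
        except Exception as exc:  # attach the covariate to propagated failures
            raise SelectionError(f"lag selection failed for {cov!r}: {exc}") from exc
    return results


def lag_map(results: list[LagSelectionResult]) -> dict[str, int]:
    """Collapse selection results into the lag map consumed by Model 3."""
    return {r.covariate: r.selected_lag for r in results}


def wsad_table(results: list[LagSelectionResult]) -> pd.DataFrame:
    """Per-covariate WSAD-by-lag table (rows: covariates, columns: lags)."""
    rows = {r.covariate: pd.Series(r.wsad_by_lag) for r in results}
    table = pd.DataFrame(rows).T
    table.index.name = "covariate"
    table.columns.name = "lag"
    return table
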