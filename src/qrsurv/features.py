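"""Design-matrix construction for the four model specifications.

Seasonal variation enters as a linear-in-parameters cosinor: paired
sine/cosine terms with periods of 365.25 and 182.625 days.  Weekly
structure enters as day-of-week indicators against a fixed reference
weekday (Sunday by default).  Weather and air-quality covariates enter
either as single selected day-lags (Model 3) or as trailing moving
averages (Model 4).  All designs are complete-case: any row with a
missing response or predictor is dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import COVARIATES, DailySeries

ANNUAL_PERIOD = 365.25
SEMIANNUAL_PERIOD = ANNUAL_PERIOD / 2.0

MODEL_NAMES = ("M1_unconditional", "M2_seasonal", "M3_seasonal_lags", "M4_seasonal_ma")

_WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class SpecError(ValueError):
    """Raised for invalid model specifications or spec/series mismatches."""


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model specifications.

    M1: intercept only.  M2: intercept + cosinor + day-of-week.
    M3: M2 + one lagged column per covariate (``lag_map`` required,
    lags in 1..7).  M4: M2 + one trailing moving-average column per
    covariate (``ma_window`` days, default 7).
    """

    name: str
    lag_map: dict[str, int] | None = None
    ma_window: int | None = None
    dow_reference: str = "Sun"

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise SpecError(f"unknown model name {self.name!r}; expected one of {MODEL_NAMES}")
        if (self.lag_map is not None) != (self.name == "M3_seasonal_lags"):
            raise SpecError("lag_map must be given exactly for M3_seasonal_lags")
        if self.lag_map is not None:
            for cov, lag in self.lag_map.items():
                if not (1 <= int(lag) <= 7):
                    raise SpecError(f"lag for {cov!r} must be in 1..7, got {lag}")
        if self.name == "M4_seasonal_ma":
            window = 7 if self.ma_window is None else self.ma_window
            if window < 2:
                raise SpecError(f"ma_window must be >= 2, got {window}")
            object.__setattr__(self, "ma_window", window)
        elif self.ma_window is not None:
            raise SpecError("ma_window only applies to M4_seasonal_ma")
        if self.dow_reference not in _WEEKDAYS:
            raise SpecError(f"dow_reference must be one of {_WEEKDAYS}")

    @classmethod
    def m1(cls) -> "ModelSpec":
        return cls("M1_unconditional")

    @classmethod
    def m2(cls, dow_reference: str = "Sun") -> "ModelSpec":
        return cls("M2_seasonal", dow_reference=dow_reference)

    @classmethod
    def m3(cls, lag_map: dict[str, int], dow_reference: str = "Sun") -> "ModelSpec":
        return cls("M3_seasonal_lags", lag_map=dict(lag_map), dow_reference=dow_reference)

    @classmethod
    def m4(cls, ma_window: int = 7, dow_reference: str = "Sun") -> "ModelSpec":
        return cls("M4_seasonal_ma", ma_window=ma_window, dow_reference=dow_reference)


@dataclass(frozen=True)
class DesignMatrix:
    """Predictors and response aligned to retained calendar days.

    ``X`` has the intercept first and no missing cells; ``dropped_days``
    counts source rows removed by lagging or missingness so that
    ``len(X) + dropped_days`` equals the source length.
    """

    dates: pd.DatetimeIndex
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    dropped_days: int

    def __post_init__(self) -> None:
        if self.X.isna().any().any() or np.isnan(self.y).any():
            raise SpecError("design matrix contains missing cells after filtering")
        if list(self.X.columns)[0] != "intercept":
            raise SpecError("intercept column must come first")
        if self.X.columns.has_duplicates:
            raise SpecError("duplicate column names in design")
        if not (self.X["intercept"] == 1.0).all():
            raise SpecError("intercept column must be identically 1")

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)


def make_cosinor(dates: pd.DatetimeIndex, origin: pd.Timestamp) -> pd.DataFrame:
    """Yearly and half-yearly cosinor columns.

    ``t`` is whole days elapsed since ``origin`` (t=0 at the origin), so
    in-sample and out-sample features share one phase convention when
    the same origin is passed for both.
    """
    if len(dates) == 0:
        raise SpecError("dates must be non-empty")
    t = (pd.DatetimeIndex(dates) - pd.Timestamp(origin)).days.to_numpy(dtype=float)
    w1 = 2.0 * np.pi * t / ANNUAL_PERIOD
    w2 = 2.0 * np.pi * t / SEMIANNUAL_PERIOD
    return pd.DataFrame(
        {
            "cos_annual": np.cos(w1),
            "sin_annual": np.sin(w1),
            "cos_semiannual": np.cos(w2),
            "sin_semiannual": np.sin(w2),
        },
        index=dates,
    )


def make_dow_dummies(dates: pd.DatetimeIndex, reference: str = "Sun") -> pd.DataFrame:
    """0/1 indicator columns for the six non-reference weekdays."""
    if reference not in _WEEKDAYS:
        raise SpecError(f"reference must be one of {_WEEKDAYS}")
    dow = pd.DatetimeIndex(dates).dayofweek  # Monday=0
    out = {}
    for i, name in enumerate(_WEEKDAYS):
        if name == reference:
            continue
        out[f"dow_{name}"] = (dow == i).astype(float)
    return pd.DataFrame(out, index=dates)


def make_lag(series: pd.Series, k: int) -> pd.Series:
    """Shift a daily series back by ``k`` days; first ``k`` days become
    missing and missing inputs propagate."""
    if k < 0 or k >= len(series):
        raise SpecError(f"lag must satisfy 0 <= k < len(series); got k={k}, len={len(series)}")
    return series.shift(k)


def make_moving_average(series: pd.Series, window: int) -> pd.Series:
    """Trailing mean of days t-window+1 .. t; missing whenever any day in
    the window is missing or the window extends before the start."""
    if window < 2:
        raise SpecError(f"window must be >= 2, got {window}")
    # min_periods=window makes any window containing a missing value NaN
    return series.rolling(window, min_periods=window).mean()


def assemble_design(
    series: DailySeries, spec: ModelSpec, origin: pd.Timestamp | None = None
) -> DesignMatrix:
    """Build the complete-case design matrix for one model specification.

    ``origin`` anchors the cosinor phase; by default the first date of
    ``series``, but evaluation passes the first date of the *full*
    dataset so both halves of a split share the phase convention.
    """
    frame = series.frame
    if origin is None:
        origin = frame.index[0]

    parts: list[pd.DataFrame] = [
        pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
    ]
    if spec.name != "M1_unconditional":
        parts.append(make_cosinor(frame.index, origin))
        parts.append(make_dow_dummies(frame.index, spec.dow_reference))
    if spec.name == "M3_seasonal_lags":
        assert spec.lag_map is not None
        for cov, lag in spec.lag_map.items():
            if cov not in COVARIATES:
                raise SpecError(f"lag_map names unknown covariate {cov!r}")
            parts.append(make_lag(frame[cov], int(lag)).to_frame(f"{cov}_lag{lag}"))
    elif spec.name == "M4_seasonal_ma":
        for cov in COVARIATES:
            parts.append(
                make_moving_average(frame[cov], int(spec.ma_window)).to_frame(
                    f"{cov}_ma{spec.ma_window}"
                )
            )

    X = pd.concat(parts, axis=1)
    y = frame["deaths"]
    keep = X.notna().all(axis=1) & y.notna()
    dropped = int((~keep).sum())
    return DesignMatrix(
        dates=frame.index[keep],
        X=X.loc[keep],
        y=y.loc[keep].to_numpy(dtype=float),
        dropped_days=dropped,
    )
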