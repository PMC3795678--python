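"""Daily mortality series container and its CSV dialect.

A :class:`DailySeries` holds one row per calendar day: a non-negative
integer death count and six weather / air-quality covariates (mean
temperature, dew point, O3, SO2, NO2, CO).  Missing values are allowed in
every data column; the calendar itself must be complete, strictly
increasing and gap-free so that day-lag arithmetic stays calendar-true.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: covariate column order used throughout the package and in the CSV dialect
COVARIATES: tuple[str, ...] = ("tmean", "dptp", "o3", "so2", "no2", "co")

#: all data columns of the CSV dialect, in order (after the leading date column)
DATA_COLUMNS: tuple[str, ...] = ("deaths",) + COVARIATES


class SeriesValidationError(ValueError):
    """Raised when a daily series violates its structural invariants."""


@dataclass(frozen=True)
class DailySeries:
    """A calendar-indexed daily table of death counts and covariates.

    Parameters
    ----------
    frame : pandas.DataFrame
        Indexed by a daily :class:`~pandas.DatetimeIndex`; columns are
        ``deaths`` plus :data:`COVARIATES`.  Missing cells are NaN.
        Present ``deaths`` values must be non-negative integers.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            raise SeriesValidationError("index must be a DatetimeIndex of calendar days")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise SeriesValidationError(f"duplicate date: {dup.date()}")
        if not f.index.is_monotonic_increasing:
            raise SeriesValidationError("dates must be strictly increasing")
        if len(f) > 1:
            deltas = np.diff(f.index.values).astype("timedelta64[D]").astype(int)
            if (deltas != 1).any():
                raise SeriesValidationError(
                    "calendar has gaps; fill them as missing rows first "
                    "(see read_csv(fill_gaps=True))"
                )
        missing_cols = [c for c in DATA_COLUMNS if c not in f.columns]
        if missing_cols:
            raise SeriesValidationError(f"missing columns: {missing_cols}")
        deaths = f["deaths"]
        present = deaths.dropna()
        if (present < 0).any():
            day = present.index[present < 0][0]
            raise SeriesValidationError(f"negative death count on {day.date()}")
        if not np.allclose(present, np.round(present), atol=1e-9):
            day = present.index[~np.isclose(present, np.round(present))][0]
            raise SeriesValidationError(f"non-integer death count on {day.date()}")

    # -- basic accessors -------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def deaths(self) -> pd.Series:
        return self.frame["deaths"]

    def covariate(self, name: str) -> pd.Series:
        if name not in COVARIATES:
            raise KeyError(f"unknown covariate {name!r}; expected one of {COVARIATES}")
        return self.frame[name]

    def __len__(self) -> int:
        return len(self.frame)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DailySeries":
        """Validate and wrap an existing day-indexed data frame."""
        absent = [c for c in DATA_COLUMNS if c not in frame.columns]
        if absent:
            raise SeriesValidationError(f"missing columns: {absent}")
        out = frame[list(DATA_COLUMNS)].astype(float)
        out.index = pd.DatetimeIndex(out.index).normalize()
        out.index.name = "date"
        return cls(out)

    @classmethod
    def read_csv(cls, path, fill_gaps: bool = True) -> "DailySeries":
        """Read the package CSV dialect (date, deaths, tmean, ..., co).

        Empty cells are missing.  With ``fill_gaps`` (the default),
        calendar gaps are materialised as all-missing rows and a warning
        is issued, so lag and moving-average alignment stays calendar-true.
        """
        raw = pd.read_csv(path)
        if "date" not in raw.columns:
            raise SeriesValidationError("CSV must have a 'date' column")
        missing_cols = [c for c in DATA_COLUMNS if c not in raw.columns]
        if missing_cols:
            raise SeriesValidationError(f"missing columns: {missing_cols}")
        try:
            idx = pd.DatetimeIndex(pd.to_datetime(raw["date"], format="ISO8601"))
        except (ValueError, TypeError) as exc:
            raise SeriesValidationError(f"unparseable date column: {exc}") from exc
        for col in DATA_COLUMNS:
            try:
                raw[col] = pd.to_numeric(raw[col])
            except (ValueError, TypeError) as exc:
                bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
                row = bad.index[0] if len(bad) else "?"
                raise SeriesValidationError(
                    f"non-numeric value in column {col!r} at row {row}"
                ) from exc
        frame = raw[list(DATA_COLUMNS)].set_axis(idx.normalize())
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise SeriesValidationError(f"duplicate date: {dup.date()}")
        if not frame.index.is_monotonic_increasing:
            raise SeriesValidationError("dates must be strictly increasing")
        full = pd.date_range(frame.index[0], frame.index[-1], freq="D")
        if len(full) != len(frame):
            n_gap = len(full) - len(frame)
            warnings.warn(
                f"calendar has {n_gap} missing day(s); inserted as all-missing rows",
                stacklevel=2,
            )
            if not fill_gaps:
                raise SeriesValidationError(f"calendar has {n_gap} missing day(s)")
            frame = frame.reindex(full)
        return cls.from_frame(frame)

    def to_csv(self, path) -> None:
        """Write the package CSV dialect; missing cells become empty fields."""
        out = self.frame.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False, float_format="%.6g")

    # -- manipulation ----------------------------------------------------
    def restrict(self, mask_or_slice) -> pd.DataFrame:
        return self.frame.loc[mask_or_slice]
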