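"""Model comparison (WSAD and R1) and exceedance classification.

The series is split at a cutoff date into a model-development half
("in-sample", prediction) and a cross-validation half ("out-sample",
forecasting).  Every model is fitted on in-sample rows only; out-sample
scores come from predicting with the frozen in-sample coefficients.
R1 is the proportionate reduction in WSAD of a conditional model over
the unconditional (intercept-only) model:

    R1 = 1 - WSAD_model / WSAD_unconditional.

Exceedance flags compare each day's count against the unconditional
quantile (one constant) and the conditional quantile (day-varying):
days above the constant but not the conditional fit are re-classified
from "unusual" to seasonally typical, and vice versa.  A day exactly on
a threshold counts as typical, consistent with the check loss giving
zero weight at equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .features import DesignMatrix, ModelSpec, assemble_design
from .quantile import QuantileModel, QuantileResults, wsad_loss
from .series import DailySeries

SAMPLES = ("in", "out")


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs."""


def split_sample(series: DailySeries, cutoff) -> tuple[DailySeries, DailySeries]:
    """Partition the series into days <= cutoff and days > cutoff."""
    cutoff = pd.Timestamp(cutoff)
    idx = series.dates
    if cutoff < idx[0] or cutoff >= idx[-1]:
        raise EvaluationError(
            f"cutoff {cutoff.date()} must lie strictly inside [{idx[0].date()}, {idx[-1].date()})"
        )
    left = DailySeries(series.frame.loc[:cutoff])
    right = DailySeries(series.frame.loc[cutoff + pd.Timedelta(days=1):])
    return left, right


def r1(wsad_model: float, wsad_null: float) -> float:
    """Proportionate reduction in WSAD over the unconditional model."""
    if not wsad_null > 0:
        raise EvaluationError(f"null WSAD must be > 0, got {wsad_null}")
    if wsad_model < 0:
        raise EvaluationError(f"model WSAD must be >= 0, got {wsad_model}")
    return 1.0 - wsad_model / wsad_null


@dataclass
class _ModelScore:
    wsad: float
    r1: float
    n_days: int
    dates: pd.DatetimeIndex = field(repr=False)
    y: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)


@dataclass
class ComparisonTable:
    """WSAD and R1 per model per sample — the model-comparison table.

    ``scores[(model, sample)]`` keeps the underlying predictions so the
    tabled WSADs can be recomputed from first principles; ``fits`` holds
    the in-sample :class:`QuantileResults` per model.
    """

    tau: float
    cutoff: pd.Timestamp
    scores: dict[tuple[str, str], _ModelScore]
    fits: dict[str, QuantileResults]
    null_model: str = "M1_unconditional"

    def wsad(self, model: str, sample: str) -> float:
        return self.scores[(model, sample)].wsad

    def r1(self, model: str, sample: str) -> float:
        return self.scores[(model, sample)].r1

    def n_days(self, model: str, sample: str) -> int:
        return self.scores[(model, sample)].n_days

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(m for (m, _) in self.scores))

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: rows (sample, metric), one column per model.

        R1 values are rounded to 3 decimals in this display form; full
        precision stays available through :meth:`r1`.
        """
        rows = {}
        for sample in SAMPLES:
            rows[(sample, "WSAD")] = {
                m: round(self.wsad(m, sample), 1) for m in self.models
            }
            rows[(sample, "R1")] = {m: round(self.r1(m, sample), 3) for m in self.models}
            rows[(sample, "days")] = {m: self.n_days(m, sample) for m in self.models}
        out = pd.DataFrame(rows).T
        out.index.names = ["sample", "metric"]
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def evaluate_models(
    series: DailySeries,
    specs: list[ModelSpec],
    tau: float = 0.9,
    cutoff=None,
    origin=None,
    jitter: float | None = None,
    jitter_seed: int | None = None,
) -> ComparisonTable:
    """Fit each specification in-sample and score both samples.

    Designs are assembled on the full series (one cosinor phase origin;
    early out-sample lags may reach back into late in-sample days, as a
    real forecast would) and then partitioned at the cutoff.  Each
    model's complete-case rows may differ — lagged models lose rows —
    so per-model day counts are reported alongside the scores.  R1 uses
    the unconditional model's WSAD of the same sample as denominator;
    out-sample predictions of the unconditional model are the frozen
    in-sample quantile, making its out-sample R1 exactly 0 as well.
    """
    if cutoff is None:
        raise EvaluationError("cutoff date is required")
    cutoff = pd.Timestamp(cutoff)
    names = [s.name for s in specs]
    if "M1_unconditional" not in names:
        raise EvaluationError("specs must include M1_unconditional (the R1 denominator)")
    if origin is None:
        origin = series.dates[0]
    idx = series.dates
    if cutoff < idx[0] or cutoff >= idx[-1]:
        raise EvaluationError(
            f"cutoff {cutoff.date()} must lie strictly inside [{idx[0].date()}, {idx[-1].date()})"
        )

    scores: dict[tuple[str, str], _ModelScore] = {}
    fits: dict[str, QuantileResults] = {}
    raw: dict[tuple[str, str], tuple] = {}
    for spec in specs:
        try:
            design = assemble_design(series, spec, origin=origin)
            in_mask = design.dates <= cutoff
            parts = {}
            for sample, mask in (("in", in_mask), ("out", ~in_mask)):
                parts[sample] = DesignMatrix(
                    dates=design.dates[mask],
                    X=design.X.loc[mask],
                    y=design.y[mask],
                    dropped_days=0,
                )
            fit = QuantileModel.from_design(parts["in"], tau=tau).fit(
                jitter=jitter, jitter_seed=jitter_seed
            )
        except Exception as exc:
            raise EvaluationError(f"model {spec.name} failed: {exc}") from exc
        fits[spec.name] = fit
        for sample in SAMPLES:
            d = parts[sample]
            pred = fit.predict(d)
            raw[(spec.name, sample)] = (d.dates, d.y, pred, wsad_loss(d.y, pred, tau))

    for (name, sample), (dates, y, pred, w) in raw.items():
        null_w = raw[("M1_unconditional", sample)][3]
        scores[(name, sample)] = _ModelScore(
            wsad=w, r1=r1(w, null_w), n_days=len(y), dates=dates, y=y, predicted=pred
        )
    # preserve the caller's model order
    ordered = {
        (s.name, sample): scores[(s.name, sample)] for s in specs for sample in SAMPLES
    }
    return ComparisonTable(tau=tau, cutoff=cutoff, scores=ordered, fits=fits)


class ExceedanceFlag(str, Enum):
    """Joint classification of a day under the unconditional and
    conditional quantile thresholds (strict exceedance; a count equal
    to a threshold is typical)."""

    TYPICAL_BOTH = "typical_both"
    UNUSUAL_BOTH = "unusual_both"
    UNUSUAL_UNCOND_ONLY = "unusual_uncond_only"  # "black triangles"
    UNUSUAL_COND_ONLY = "unusual_cond_only"      # "larger dots"


def flag_exceedance(y, q_uncond: float, q_cond) -> np.ndarray:
    """Classify each day's count against both quantile thresholds.

    Returns an object array of :class:`ExceedanceFlag`; the four
    categories partition the days.
    """
    y = np.asarray(y, dtype=float)
    q_cond = np.asarray(q_cond, dtype=float)
    if q_cond.shape != y.shape:
        raise EvaluationError(
            f"length mismatch: y has shape {y.shape}, q_cond has shape {q_cond.shape}"
        )
    above_u = y > q_uncond
    above_c = y > q_cond
    out = np.empty(y.shape, dtype=object)
    out[~above_u & ~above_c] = ExceedanceFlag.TYPICAL_BOTH
    out[above_u & above_c] = ExceedanceFlag.UNUSUAL_BOTH
    out[above_u & ~above_c] = ExceedanceFlag.UNUSUAL_UNCOND_ONLY
    out[~above_u & above_c] = ExceedanceFlag.UNUSUAL_COND_ONLY
    return out


def exceedance_frame(dates, y, q_uncond: float, q_cond) -> pd.DataFrame:
    """Per-day exceedance report (date, deaths, thresholds, flag)."""
    flags = flag_exceedance(y, q_uncond, q_cond)
    return pd.DataFrame(
        {
            "deaths": np.asarray(y, dtype=float),
            "q_uncond": float(q_uncond),
            "q_cond": np.asarray(q_cond, dtype=float),
            "flag": [f.value for f in flags],
        },
        index=pd.DatetimeIndex(dates, name="date"),
    )
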