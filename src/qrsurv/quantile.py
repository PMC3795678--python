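"""Linear conditional-quantile estimation by exact check-loss minimisation.

The criterion is the weighted sum of absolute deviations (WSAD)

    L(beta) = (1 - tau) * sum_{y_i < q_i} |y_i - q_i|
            +       tau * sum_{y_i > q_i} |y_i - q_i|,      q_i = x_i' beta,

minimised exactly through its linear-programming equivalent: residuals
are split into positive and negative parts weighted tau and 1-tau, and
the LP is solved with the HiGHS dual simplex so the reported solution is
a basic (vertex) solution.  For an intercept-only design this vertex
coincides with the lower order statistic whenever n*tau is an integer,
the convention :func:`unconditional_quantile` implements directly.

Counts may optionally be "jittered" — additive uniform noise on
[-amount, +amount] applied to the response before fitting — so the
optimisation behaves as for a continuous response; the default is no
jitter.

The public surface follows the statsmodels idiom: build a
:class:`QuantileModel` from data (or :meth:`QuantileModel.from_design`),
call :meth:`~QuantileModel.fit`, and work with the returned
:class:`QuantileResults`.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import qr as _qr
from scipy.optimize import linprog

from .features import DesignMatrix

_RANK_TOL = 1e-10
_LP_TOL = 1e-9


class FitError(RuntimeError):
    """Raised when a quantile fit cannot be computed."""


def wsad_loss(y: Sequence[float], q: Sequence[float], tau: float) -> float:
    """Weighted sum of absolute deviations of predictions ``q`` from ``y``.

    Deviations below the predicted quantile are weighted ``1 - tau`` and
    deviations above it ``tau``; exact hits contribute nothing.
    """
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    if y.shape != q.shape:
        raise ValueError(f"length mismatch: y has shape {y.shape}, q has shape {q.shape}")
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie strictly in (0, 1), got {tau}")
    r = y - q
    return float(np.sum(np.where(r > 0, tau * r, (tau - 1.0) * r)))


def unconditional_quantile(y: Sequence[float], tau: float = 0.9) -> float:
    """Empirical ``tau``-quantile under the lower-order-statistic convention.

    Equals the intercept reported by :class:`QuantileModel` on an
    intercept-only design: the k-th smallest value with k = ceil(n*tau),
    taking the lower order statistic (k = n*tau) when n*tau is an integer.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y must be non-empty")
    if np.isnan(y).any():
        raise ValueError("y must not contain missing values")
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie strictly in (0, 1), got {tau}")
    n = y.size
    m = n * tau
    k = int(round(m)) if abs(m - round(m)) < 1e-9 else int(np.ceil(m))
    k = max(k, 1)
    return float(np.sort(y)[k - 1])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = _RANK_TOL * max(X.shape) * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise FitError(f"design is rank-deficient; collinear columns: {bad}")


class QuantileModel:
    """Linear model for a conditional quantile of a daily count.

    Parameters
    ----------
    endog : array-like
        Response (daily death counts), no missing values.
    exog : pandas.DataFrame or array-like
        Predictor columns, intercept included by the caller.
    tau : float
        Quantile level in (0, 1); 0.9 targets higher-than-expected days.
    """

    def __init__(self, endog, exog, tau: float = 0.9) -> None:
        if not (0.0 < tau < 1.0):
            raise ValueError(f"tau must lie strictly in (0, 1), got {tau}")
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.exog_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("missing values in endog/exog; filter before fitting")
        if X.shape[0] < X.shape[1] + 1:
            raise FitError(
                f"need at least {X.shape[1] + 1} rows to fit {X.shape[1]} coefficients, "
                f"got {X.shape[0]}"
            )
        self.endog = y
        self.exog = X
        self.tau = float(tau)

    @classmethod
    def from_design(cls, design: DesignMatrix, tau: float = 0.9) -> "QuantileModel":
        """Build the model from an assembled :class:`DesignMatrix`."""
        model = cls(design.y, design.X, tau=tau)
        model._dates = design.dates
        return model

    def fit(
        self, jitter: float | None = None, jitter_seed: int | None = None
    ) -> "QuantileResults":
        """Minimise the check loss exactly; returns :class:`QuantileResults`.

        With ``jitter`` set, uniform noise on [-jitter, +jitter] (drawn
        with ``jitter_seed``) is added to the response before solving;
        the training WSAD refers to the response actually fitted.
        """
        y = self.endog
        jitter_meta = {"applied": False, "amount": 0.0, "seed": None}
        if jitter is not None:
            if jitter < 0:
                raise ValueError("jitter amount must be non-negative")
            if jitter_seed is None:
                raise ValueError("jitter requires an explicit jitter_seed for reproducibility")
            rng = np.random.default_rng(jitter_seed)
            y = y + rng.uniform(-jitter, jitter, size=y.size)
            jitter_meta = {"applied": True, "amount": float(jitter), "seed": int(jitter_seed)}

        X = self.exog
        _check_rank(X, self.exog_names)
        n, p = X.shape
        tau = self.tau
        # min tau*1'u + (1-tau)*1'v  s.t.  X beta + u - v = y, u, v >= 0
        c = np.concatenate([np.zeros(p), tau * np.ones(n), (1.0 - tau) * np.ones(n)])
        A = sp.hstack([sp.csr_matrix(X), sp.eye(n, format="csr"), -sp.eye(n, format="csr")])
        bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
        res = linprog(
            c,
            A_eq=A,
            b_eq=y,
            bounds=bounds,
            method="highs-ds",
            options={"primal_feasibility_tolerance": _LP_TOL, "dual_feasibility_tolerance": _LP_TOL},
        )
        if res.status != 0:
            raise FitError(f"LP solver failed (status {res.status}): {res.message}")
        beta = res.x[:p]
        params = pd.Series(beta, index=self.exog_names, name="coef")
        train_wsad = wsad_loss(y, X @ beta, tau)
        return QuantileResults(self, params, train_wsad, jitter_meta)


class QuantileResults:
    """Fitted conditional-quantile model.

    Attributes
    ----------
    params : pandas.Series
        Named coefficients (beta).
    train_wsad : float
        Check-loss value at the optimum, on the response actually fitted.
    n_used : int
        Rows used in the fit.
    """

    def __init__(
        self,
        model: QuantileModel,
        params: pd.Series,
        train_wsad: float,
        jitter_meta: dict,
    ) -> None:
        self.model = model
        self.params = params
        self.tau = model.tau
        self.n_used = int(model.exog.shape[0])
        self.train_wsad = float(train_wsad)
        self.jitter = dict(jitter_meta)
        if self.train_wsad < -1e-9:
            raise FitError("negative training WSAD; solver failure")

    # -- prediction ------------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params.to_numpy()

    def predict(self, design) -> np.ndarray:
        """Predicted conditional quantiles x'beta; no re-estimation.

        Accepts a :class:`DesignMatrix`, a DataFrame with matching
        columns, or a plain array with matching width.
        """
        if isinstance(design, DesignMatrix):
            design = design.X
        if isinstance(design, pd.DataFrame):
            if list(design.columns) != list(self.params.index):
                raise ValueError(
                    f"design columns {list(design.columns)} do not match "
                    f"fitted coefficients {list(self.params.index)}"
                )
            X = design.to_numpy(dtype=float)
        else:
            X = np.asarray(design, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[1] != self.params.size:
                raise ValueError("design width does not match number of coefficients")
        return X @ self.params.to_numpy()

    # -- diagnostics -----------------------------------------------------
    def quantile_balance(self) -> dict[str, float]:
        """Counts of observations strictly below/above the fitted quantile.

        LP optimality implies #below <= n*tau and #above <= n*(1-tau).
        """
        q = self.fittedvalues
        y = self.model.endog
        return {
            "n": float(y.size),
            "n_below": float(np.sum(y < q - 1e-9)),
            "n_above": float(np.sum(y > q + 1e-9)),
            "tau": self.tau,
        }

    def summary(self) -> str:
        bal = self.quantile_balance()
        lines = [
            "Conditional quantile regression (check-loss minimisation)",
            "=" * 60,
            f"tau: {self.tau:<10} n: {self.n_used:<8} train WSAD: {self.train_wsad:.4f}",
            f"jitter: {'+/-%g (seed %s)' % (self.jitter['amount'], self.jitter['seed']) if self.jitter['applied'] else 'none'}",
            f"obs below fit: {int(bal['n_below'])} (<= n*tau = {bal['n'] * self.tau:.1f})   "
            f"obs above fit: {int(bal['n_above'])} (<= n*(1-tau) = {bal['n'] * (1 - self.tau):.1f})",
            "-" * 60,
            f"{'term':<20}{'coef':>12}",
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<20}{val:>12.4f}")
        lines.append("=" * 60)
        lines.append("Standard errors are deliberately not reported; model choice")
        lines.append("rests on predictive/forecast WSAD and R1, not on coefficients.")
        return "\n".join(lines)

    # -- serialisation ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "tau": self.tau,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "n_used": self.n_used,
            "train_wsad": self.train_wsad,
            "jitter": self.jitter,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
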