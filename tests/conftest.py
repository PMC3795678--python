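import numpy as np
import pandas as pd
import pytest

from qrsurv.synthetic import CovariateEffect, SyntheticConfig, generate

#: standard-normal 0.9 quantile, used to centre noise so its q90 is zero
Z90 = 1.2815515655446004


def linear_quantile_data(seed: int, n: int, beta, sigma: float = 3.0, tau: float = 0.9):
    """Data whose true conditional tau-quantile is exactly X @ beta.

    Gaussian noise is shifted so its tau-quantile is zero; columns are
    an intercept plus standard-normal covariates.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p > 1 else np.ones((n, 1))
    from scipy.stats import norm

    y = X @ beta + sigma * (rng.normal(size=n) - norm.ppf(tau))
    cols = ["intercept"] + [f"x{i}" for i in range(1, p)]
    return pd.DataFrame(X, columns=cols), y


@pytest.fixture(scope="session")
def small_series():
    """An 800-day paper-like synthetic series with mild missingness."""
    cfg = SyntheticConfig(
        n_days=800,
        missing_rate=0.005,
        covariate_effects={"tmean": CovariateEffect(3, -0.1), "no2": CovariateEffect(1, 0.05)},
        seed=42,
    )
    series, truth = generate(cfg)
    return series, truth


@pytest.fixture(scope="session")
def complete_series():
    """A fully observed 400-day series with no covariate effects."""
    cfg = SyntheticConfig(n_days=400, missing_rate=0.0, seed=7)
    series, truth = generate(cfg)
    return series, truth
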