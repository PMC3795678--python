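import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrsurv.features import ModelSpec, assemble_design
from qrsurv.quantile import (
    FitError,
    QuantileModel,
    unconditional_quantile,
    wsad_loss,
)

from .conftest import linear_quantile_data
from .oracles import check_loss, grid_search_quantile, vertex_enumeration


class TestWsadLoss:
    @pytest.mark.parametrize(
        "y, q, tau, expected",
        [
            ([1, 2, 3], [2, 2, 2], 0.9, 0.1 * 1 + 0.9 * 1),
            ([5, 5], [5, 5], 0.9, 0.0),
            ([0, 10], [5, 5], 0.5, 0.5 * 5 + 0.5 * 5),
        ],
    )
    def test_direct_arithmetic(self, y, q, tau, expected):
        assert wsad_loss(y, q, tau) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            wsad_loss([1, 2], [1], 0.9)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_independent_formula(self, y, tau):
        q = np.zeros(len(y))
        assert wsad_loss(y, q, tau) == pytest.approx(check_loss(y, q, tau))


class TestUnconditionalQuantile:
    def test_constant_data(self):
        assert unconditional_quantile([5, 5, 5], 0.3) == 5.0

    def test_vertex_convention_integer_ntau(self):
        """n*tau integer: the lower order statistic, matching the LP
        vertex and the brute-force grid optimum."""
        y = np.arange(1.0, 11.0)
        assert unconditional_quantile(y, 0.9) == 9.0
        _, grid_loss = grid_search_quantile(y, 0.9)
        assert check_loss(y, np.full(10, 9.0), 0.9) == pytest.approx(grid_loss, abs=1e-3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=31)
        for _ in range(5):
            assert unconditional_quantile(rng.permutation(y), 0.9) == unconditional_quantile(
                y, 0.9
            )

    def test_agrees_with_intercept_only_fit(self):
        rng = np.random.default_rng(5)
        for seed in range(8):
            y = np.round(np.random.default_rng(seed).gamma(5, 3, size=37))
            for tau in (0.5, 0.9):
                res = QuantileModel(y, np.ones((y.size, 1)), tau=tau).fit()
                assert res.params.iloc[0] == pytest.approx(
                    unconditional_quantile(y, tau), abs=1e-8
                )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            unconditional_quantile([], 0.9)


class TestFit:
    def test_exact_interpolation_recovers_line(self):
        x = np.linspace(0, 10, 25)
        y = 2.0 + 3.0 * x
        X = pd.DataFrame({"intercept": np.ones(25), "x": x})
        for tau in (0.25, 0.5, 0.9):
            res = QuantileModel(y, X, tau=tau).fit()
            assert res.params["intercept"] == pytest.approx(2.0, abs=1e-8)
            assert res.params["x"] == pytest.approx(3.0, abs=1e-8)
            assert res.train_wsad == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle_intercept_only(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0])
        for tau in (0.5, 0.9):
            res = QuantileModel(y, np.ones((11, 1)), tau=tau).fit()
            q_grid, loss_grid = grid_search_quantile(y, tau)
            assert res.train_wsad == pytest.approx(loss_grid, abs=1e-3)
            assert res.params.iloc[0] == pytest.approx(q_grid, abs=1e-3)

    def test_matches_vertex_enumeration(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 13))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 1))])
            y = X @ np.array([2.0, -1.0]) + rng.normal(size=n)
            for tau in (0.5, 0.9):
                res = QuantileModel(y, X, tau=tau).fit()
                beta, loss = vertex_enumeration(X, y, tau)
                assert res.train_wsad == pytest.approx(loss, abs=1e-9)
                np.testing.assert_allclose(X @ res.params.to_numpy(), X @ beta, atol=1e-7)

    def test_matches_statsmodels_irls(self):
        """statsmodels QuantReg (IRLS, an algorithmically independent
        route) agrees in fitted values to its own numerical resolution."""
        import statsmodels.api as sm

        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(25, 41))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = X @ rng.normal(size=3) + rng.normal(size=n)
            tau = (0.5, 0.9)[seed % 2]
            res = QuantileModel(y, X, tau=tau).fit()
            sm_res = sm.QuantReg(y, X).fit(q=tau, p_tol=1e-12, max_iter=5000)
            np.testing.assert_allclose(
                X @ res.params.to_numpy(), X @ sm_res.params, atol=1e-4
            )

    def test_quantile_sign_property(self):
        for seed in range(5):
            X, y = linear_quantile_data(seed, 200, [15.0, 2.0, -1.0])
            for tau in (0.5, 0.9):
                res = QuantileModel(y, X, tau=tau).fit()
                bal = res.quantile_balance()
                assert bal["n_below"] <= 200 * tau
                assert bal["n_above"] <= 200 * (1 - tau)

    def test_location_equivariance(self):
        X, y = linear_quantile_data(3, 120, [10.0, 1.5])
        r0 = QuantileModel(y, X, tau=0.9).fit()
        r1 = QuantileModel(y + 7.5, X, tau=0.9).fit()
        assert r1.params["intercept"] == pytest.approx(r0.params["intercept"] + 7.5, abs=1e-8)
        assert r1.params["x1"] == pytest.approx(r0.params["x1"], abs=1e-8)

    def test_positive_scale_equivariance(self):
        X, y = linear_quantile_data(4, 120, [10.0, 1.5])
        r0 = QuantileModel(y, X, tau=0.9).fit()
        r1 = QuantileModel(3.0 * y, X, tau=0.9).fit()
        np.testing.assert_allclose(r1.params, 3.0 * r0.params, atol=1e-7)

    def test_tiling_rows_preserves_solution(self):
        """Replicating every observation scales the criterion linearly,
        leaving coefficients (hence any argmin comparison) unchanged."""
        X, y = linear_quantile_data(6, 60, [12.0, -2.0])
        r0 = QuantileModel(y, X, tau=0.9).fit()
        X2 = pd.concat([X, X], ignore_index=True)
        r2 = QuantileModel(np.tile(y, 2), X2, tau=0.9).fit()
        np.testing.assert_allclose(r2.params, r0.params, atol=1e-7)
        assert r2.train_wsad == pytest.approx(2 * r0.train_wsad, rel=1e-9)

    def test_rank_deficiency_names_columns(self):
        n = 30
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x, "x_copy": x})
        with pytest.raises(FitError, match="x_copy|x"):
            QuantileModel(rng.normal(size=n), X, tau=0.9).fit()

    def test_too_few_rows(self):
        with pytest.raises(FitError, match="rows"):
            QuantileModel(np.ones(3), np.ones((3, 3)), tau=0.9)


class TestJitter:
    def test_deterministic_given_seed(self):
        X, y = linear_quantile_data(8, 100, [10.0, 1.0])
        y = np.round(y)
        r1 = QuantileModel(y, X, tau=0.9).fit(jitter=0.1, jitter_seed=5)
        r2 = QuantileModel(y, X, tau=0.9).fit(jitter=0.1, jitter_seed=5)
        pd.testing.assert_series_equal(r1.params, r2.params)
        assert r1.jitter == {"applied": True, "amount": 0.1, "seed": 5}

    def test_seed_required(self):
        X, y = linear_quantile_data(8, 50, [10.0])
        with pytest.raises(ValueError, match="seed"):
            QuantileModel(y, X).fit(jitter=0.1)

    def test_small_jitter_barely_moves_fit(self):
        X, y = linear_quantile_data(9, 300, [12.0, 2.0])
        y = np.round(y)
        r0 = QuantileModel(y, X, tau=0.9).fit()
        r1 = QuantileModel(y, X, tau=0.9).fit(jitter=0.1, jitter_seed=1)
        np.testing.assert_allclose(r1.params, r0.params, atol=0.25)


class TestPredict:
    def test_training_predictions_reproduce_wsad(self):
        X, y = linear_quantile_data(10, 150, [14.0, 1.0, -0.5])
        res = QuantileModel(y, X, tau=0.9).fit()
        assert wsad_loss(y, res.predict(X), 0.9) == pytest.approx(res.train_wsad, abs=1e-9)

    def test_constant_prediction_contract(self):
        """An intercept-only fit predicts its constant (e.g. an
        unconditional 90th percentile of 20.2 deaths/day) everywhere."""
        res = QuantileModel(
            np.full(20, 20.2), np.ones((20, 1)), tau=0.9
        ).fit()
        out = res.predict(np.ones((7, 1)))
        np.testing.assert_allclose(out, 20.2)

    def test_zero_coefficient_column_is_inert(self):
        X, y = linear_quantile_data(11, 100, [10.0, 2.0])
        res = QuantileModel(y, X, tau=0.9).fit()
        res.params["x1"] = 0.0
        X2 = X.copy()
        X2["x1"] *= 2.0
        np.testing.assert_allclose(res.predict(X2), res.predict(X))

    def test_column_mismatch_rejected(self, complete_series):
        series, _ = complete_series
        d2 = assemble_design(series, ModelSpec.m2())
        d1 = assemble_design(series, ModelSpec.m1())
        res = QuantileModel.from_design(d1, tau=0.9).fit()
        with pytest.raises(ValueError, match="column"):
            res.predict(d2.X)


class TestSerialization:
    def test_json_roundtrip_fields(self, tmp_path):
        X, y = linear_quantile_data(12, 80, [11.0, 1.0])
        res = QuantileModel(y, X, tau=0.9).fit()
        path = tmp_path / "fit.json"
        res.to_json(path)
        data = json.loads(path.read_text())
        assert data["tau"] == 0.9
        assert data["n_used"] == 80
        assert data["coefficients"]["intercept"] == pytest.approx(res.params["intercept"])
        assert data["jitter"]["applied"] is False

    def test_summary_mentions_key_quantities(self):
        X, y = linear_quantile_data(13, 60, [10.0])
        res = QuantileModel(y, X, tau=0.9).fit()
        text = res.summary()
        assert "tau" in text and "WSAD" in text and "intercept" in text
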