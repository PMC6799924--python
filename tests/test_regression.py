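"""Tests for Pearson screening, OLS fits and stepwise selection."""

import numpy as np
import pytest

from conftest import make_dataset
from planacast.regression import (
    RegressionModel,
    fit_regression,
    pearson_by_cycle,
    stepwise_select,
)
from planacast.zonal import COUNT_COLUMN


def dataset_from_lags(lag_values: dict, counts, blocks_per_cycle=None):
    """Dataset where every row is its own cycle unless stated otherwise."""
    ds = make_dataset({COUNT_COLUMN: counts,
                       **{f"rh_T{k}": v for k, v in lag_values.items()}})
    if blocks_per_cycle is not None:
        n = len(ds.frame)
        ds.frame["cycle_index"] = np.arange(n) // blocks_per_cycle
    return ds


class TestPearsonByCycle:
    def test_perfect_positive_and_negative(self):
        rh = np.array([50.0, 55.0, 60.0, 65.0, 70.0])
        for slope, expected in [(0.3, 1.0), (-0.3, -1.0)]:
            ds = dataset_from_lags({1: rh}, 2.0 + slope * rh, blocks_per_cycle=5)
            table = pearson_by_cycle(ds)
            row = table.frame[table.frame["lag"] == 1].iloc[0]
            assert row["r"] == pytest.approx(expected)
            assert row["stars"] != ""

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(47, 71, 10)
        y = rng.uniform(0, 12, 10)
        ds = dataset_from_lags({3: x}, y, blocks_per_cycle=10)
        row = pearson_by_cycle(ds).frame.query("lag == 3").iloc[0]
        # from-scratch covariance / sigma computation
        r_expected = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std()
        )
        assert row["r"] == pytest.approx(r_expected, rel=1e-12)
        assert row["n"] == 10

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(47, 71, 12)
        y = rng.uniform(0, 12, 12)
        base = pearson_by_cycle(
            dataset_from_lags({2: x}, y, blocks_per_cycle=12)
        ).frame.iloc[0]["r"]
        scaled = pearson_by_cycle(
            dataset_from_lags({2: 3.5 * x + 10.0}, y, blocks_per_cycle=12)
        ).frame.iloc[0]["r"]
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_zero_variance_row_omitted(self):
        ds = dataset_from_lags({1: np.full(6, 55.0)}, np.arange(6.0),
                               blocks_per_cycle=6)
        table = pearson_by_cycle(ds)
        assert table.frame[table.frame["lag"] == 1].empty
        assert any("zero variance" in entry for entry in table.log_entries)

    def test_star_thresholds(self):
        from planacast.regression import _stars

        assert _stars(0.04) == "*"
        assert _stars(0.009) == "**"
        assert _stars(0.0009) == "***"
        assert _stars(0.00009) == "****"
        assert _stars(0.2) == ""


class TestFitRegression:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(1)
        t1 = rng.uniform(47, 71, 30)
        ds = dataset_from_lags({1: t1}, 5.0 - 0.2 * t1)
        model = fit_regression(ds, [1], degree=1)
        assert model.intercept == pytest.approx(5.0, abs=1e-9)
        assert model.coefficients[0] == pytest.approx(-0.2, abs=1e-9)

    def test_noiseless_quadratic_recovery(self):
        rng = np.random.default_rng(2)
        t2 = rng.uniform(47, 71, 30)
        y = 3.0 + 0.5 * t2 - 0.01 * t2**2
        model = fit_regression(dataset_from_lags({2: t2}, y), [2], degree=2)
        assert model.intercept == pytest.approx(3.0, abs=1e-6)
        coeffs = dict(zip(model.terms, model.coefficients))
        assert coeffs[(2, 1)] == pytest.approx(0.5, abs=1e-8)
        assert coeffs[(2, 2)] == pytest.approx(-0.01, abs=1e-9)

    def test_constant_target_null_model(self):
        rng = np.random.default_rng(3)
        ds = dataset_from_lags({1: rng.uniform(47, 71, 20)}, np.full(20, 4.0))
        model = fit_regression(ds, [1], degree=1)
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert model.fit_stats["adjusted_r2"] <= 0.0

    def test_rank_deficient_design_named(self):
        ds = dataset_from_lags({1: np.full(20, 55.0)}, np.arange(20.0))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_regression(ds, [1], degree=1)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        lags = {k: rng.uniform(47, 71, 50) for k in (1, 2, 3)}
        y = rng.uniform(0, 12, 50)
        ds = dataset_from_lags(lags, y)
        model = fit_regression(ds, [1, 2, 3], degree=2)
        resid = y - model.predict_frame(ds.frame)
        assert abs(resid.sum()) < 1e-8
        for lag, power in model.terms:
            assert abs(resid @ ds.frame[f"rh_T{lag}"].to_numpy() ** power) < 1e-6

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        t1 = rng.uniform(47, 71, 40)
        y = 8.0 - 0.1 * t1 + rng.normal(0, 0.5, 40)
        model = fit_regression(dataset_from_lags({1: t1}, y), [1], degree=1)
        ref = sm.OLS(y, sm.add_constant(t1)).fit()
        assert model.intercept == pytest.approx(ref.params[0], rel=1e-9)
        assert model.coefficients[0] == pytest.approx(ref.params[1], rel=1e-9)
        assert model.fit_stats["adjusted_r2"] == pytest.approx(ref.rsquared_adj,
                                                               rel=1e-9)

    def test_r2_never_drops_and_adjustment_closed_form(self):
        rng = np.random.default_rng(6)
        lags = {k: rng.uniform(47, 71, 40) for k in (1, 2)}
        y = rng.uniform(0, 12, 40)
        ds = dataset_from_lags(lags, y)
        m1 = fit_regression(ds, [1], degree=1)
        m2 = fit_regression(ds, [1, 2], degree=1)
        assert m2.fit_stats["r2"] >= m1.fit_stats["r2"] - 1e-12
        for m, p in [(m1, 1), (m2, 2)]:
            n, r2 = m.fit_stats["n"], m.fit_stats["r2"]
            assert m.fit_stats["adjusted_r2"] == pytest.approx(
                1 - (1 - r2) * (n - 1) / (n - p - 1)
            )


class TestPredict:
    def test_published_single_lag_models_at_zero_rh(self):
        linear = RegressionModel(intercept=15.81, terms=((1, 1),),
                                 coefficients=(-0.23,), degree=1)
        poly = RegressionModel(intercept=55.45, terms=((1, 1), (1, 2)),
                               coefficients=(-1.62, 0.01), degree=2)
        assert linear.predict({1: 0.0}) == pytest.approx(15.81)
        assert poly.predict({1: 0.0}) == pytest.approx(55.45)
        # arbitrary RH, exact arithmetic on the stored coefficients
        assert linear.predict({1: 60.0}) == pytest.approx(15.81 - 0.23 * 60)
        assert poly.predict({1: 60.0}) == pytest.approx(
            55.45 - 1.62 * 60 + 0.01 * 3600
        )

    def test_zero_coefficient_model_returns_intercept(self):
        model = RegressionModel(intercept=2.5, terms=(), coefficients=())
        assert model.predict({}) == 2.5
        assert model.predict({1: 99.0}) == 2.5

    def test_missing_lag_value_raises(self):
        model = RegressionModel(intercept=0.0, terms=((3, 1),), coefficients=(1.0,))
        with pytest.raises(KeyError, match="T3"):
            model.predict({1: 50.0})

    def test_json_round_trip(self):
        model = RegressionModel(intercept=1.5, terms=((1, 1), (6, 2)),
                                coefficients=(-0.2, 0.01), degree=2,
                                fit_stats={"n": 10})
        back = RegressionModel.from_json(model.to_json())
        assert back == model


class TestStepwiseSelect:
    @staticmethod
    def noisy_dataset(informative_lag=3, n=80, seed=9):
        rng = np.random.default_rng(seed)
        lags = {k: rng.uniform(47, 71, n) for k in range(1, 7)}
        y = 10.0 - 0.4 * lags[informative_lag] + rng.normal(0, 0.5, n)
        return dataset_from_lags(lags, y)

    def test_single_informative_lag_selected(self):
        ds = self.noisy_dataset(informative_lag=3)
        model = stepwise_select(ds, degree=1)
        selected = {lag for lag, _ in model.terms}
        assert 3 in selected
        # all-subsets oracle: the best single-lag fit identifies the winner
        best = max(range(1, 7),
                   key=lambda k: fit_regression(ds, [k], 1).fit_stats["r2"])
        assert best == 3

    def test_all_noise_gives_intercept_only(self):
        rng = np.random.default_rng(10)
        lags = {k: rng.uniform(47, 71, 60) for k in range(1, 7)}
        ds = dataset_from_lags(lags, rng.normal(5, 1, 60))
        model = stepwise_select(ds, degree=1, entry_p=0.05, stay_p=0.05)
        assert model.terms == ()
        assert model.predict({}) == pytest.approx(
            float(ds.frame[COUNT_COLUMN].mean())
        )

    def test_duplicated_column_kept_once(self):
        rng = np.random.default_rng(11)
        t1 = rng.uniform(47, 71, 60)
        y = 12.0 - 0.5 * t1 + rng.normal(0, 0.3, 60)
        lags = {k: rng.uniform(47, 71, 60) for k in range(3, 7)}
        ds = dataset_from_lags({1: t1, 2: t1, **lags}, y)  # T2 duplicates T1
        model = stepwise_select(ds, degree=1)
        selected = {lag for lag, _ in model.terms}
        assert len(selected & {1, 2}) == 1
        assert 1 in selected  # tie broken toward the smaller lag index

    def test_degree2_brings_both_powers(self):
        rng = np.random.default_rng(12)
        t1 = rng.uniform(47, 71, 80)
        y = 50.0 - 1.5 * t1 + 0.012 * t1**2 + rng.normal(0, 0.2, 80)
        model = stepwise_select(dataset_from_lags({1: t1}, y,), degree=2,
                                candidate_lags=[1])
        assert set(model.terms) == {(1, 1), (1, 2)}

    def test_trace_recorded(self):
        model = stepwise_select(self.noisy_dataset(), degree=1)
        assert model.selection_trace
        assert model.selection_trace[0]["action"] == "add"
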