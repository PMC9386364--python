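import numpy as np
import pandas as pd
import pytest

from wtvi.errors import DegenerateDataError, InputError
from wtvi.fusion import (
    fit_linear,
    fuse,
    kfold_evaluate,
    kfold_split,
    plot_vi,
    rank_indices,
)
from wtvi.indices import VIImage
from wtvi.raster_io import PlotROI


def normal_equations(x, y):
    """Independent OLS oracle: solve X'X b = X'y explicitly."""
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    return slope, intercept


class TestPlotVi:
    def test_constant_mean(self):
        vi = VIImage(np.full((8, 8), 0.6), "NDVI", np.ones((8, 8), bool))
        assert plot_vi(vi, PlotROI("p", 0, 0, 8, 8)) == pytest.approx(0.6)

    def test_half_and_half(self):
        vals = np.full((8, 8), 0.2)
        vals[4:, :] = 0.4
        vi = VIImage(vals, "NDVI", np.ones((8, 8), bool))
        assert plot_vi(vi, PlotROI("p", 0, 0, 8, 8)) == pytest.approx(0.3)

    def test_all_invalid_errors(self):
        vi = VIImage(np.zeros((4, 4)), "NDVI", np.zeros((4, 4), bool))
        with pytest.raises(DegenerateDataError):
            plot_vi(vi, PlotROI("p", 0, 0, 4, 4))

    def test_invalid_pixels_excluded(self):
        vals = np.full((2, 2), 0.5)
        vals[0, 0] = 99.0
        valid = np.ones((2, 2), bool)
        valid[0, 0] = False
        vi = VIImage(vals, "NDVI", valid)
        assert plot_vi(vi, PlotROI("p", 0, 0, 2, 2)) == pytest.approx(0.5)


class TestFuse:
    def test_product(self):
        assert fuse(0.5, 0.8) == pytest.approx(0.4)

    def test_identity_element(self):
        assert fuse(0.7321, 1.0) == 0.7321

    def test_sign_preserved(self):
        assert fuse(-0.1, 0.3) == pytest.approx(-0.03)

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            fuse(float("nan"), 1.0)
        with pytest.raises(InputError):
            fuse(0.5, float("inf"))


class TestFitLinear:
    def test_noiseless_line(self):
        x = np.arange(10.0)
        m = fit_linear(x, 2 * x + 1)
        assert m.slope == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_guarded(self):
        with pytest.raises(DegenerateDataError):
            fit_linear(np.arange(5.0), np.full(5, 3.0))

    def test_zero_variance_feature(self):
        with pytest.raises(DegenerateDataError):
            fit_linear(np.full(5, 1.0), np.arange(5.0))

    def test_too_few_samples(self):
        with pytest.raises(DegenerateDataError):
            fit_linear(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_six_point_normal_equation_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.9, 5.2, 6.8, 9.1, 11.0])
        m = fit_linear(x, y)
        slope, intercept = normal_equations(x, y)
        assert m.slope == pytest.approx(slope, abs=1e-10)
        assert m.intercept == pytest.approx(intercept, abs=1e-10)
        # frozen values from the closed-form normal equations
        assert m.slope == pytest.approx(35.1 / 17.5, abs=1e-12)
        assert m.intercept == pytest.approx(6.0 - (35.1 / 17.5) * 2.5, abs=1e-12)

    def test_matches_normal_equations_on_random_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = 1.5 * x + rng.normal(size=30)
            m = fit_linear(x, y)
            slope, intercept = normal_equations(x, y)
            assert m.slope == pytest.approx(slope, abs=1e-10)
            assert m.intercept == pytest.approx(intercept, abs=1e-10)

    def test_metric_definitions(self, rng):
        x = rng.uniform(size=50)
        y = 2 * x + rng.normal(0, 0.1, size=50)
        m = fit_linear(x, y)
        pred = m.slope * x + m.intercept
        ss_res = ((y - pred) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(ss_res / 50), abs=1e-12)
        assert m.rrmse == pytest.approx(100 * m.rmse / y.mean(), abs=1e-10)


class TestKfoldSplit:
    def test_partition_disjoint_exhaustive(self):
        folds = kfold_split(20, 10, seed=3)
        assert all(len(f) == 2 for f in folds)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(20))

    def test_remainder_distributed_from_first(self):
        folds = kfold_split(23, 5, seed=0)
        assert [len(f) for f in folds] == [5, 5, 5, 4, 4]

    def test_seed_reproducible(self):
        a = kfold_split(50, 7, seed=11)
        b = kfold_split(50, 7, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_bounds(self):
        with pytest.raises(InputError):
            kfold_split(5, 1, seed=0)
        with pytest.raises(InputError):
            kfold_split(5, 6, seed=0)


class TestKfoldEvaluate:
    def test_noiseless_line_perfect(self):
        x = np.linspace(0, 1, 30)
        for k in (2, 5, 10):
            res = kfold_evaluate(x, 4 * x + 2, k=k, seed=k)
            assert res.mean_r2 == pytest.approx(1.0, abs=1e-10)
            assert res.mean_rmse == pytest.approx(0.0, abs=1e-10)

    def test_aggregates_are_fold_means(self, rng):
        x = rng.uniform(size=60)
        y = 3 * x + rng.normal(0, 0.3, size=60)
        res = kfold_evaluate(x, y, k=6, seed=9)
        assert res.mean_r2 == pytest.approx(np.mean(res.fold_r2), abs=1e-15)
        assert res.mean_rmse == pytest.approx(np.mean(res.fold_rmse), abs=1e-15)
        assert res.mean_rrmse == pytest.approx(np.mean(res.fold_rrmse), abs=1e-15)
        assert res.mean_coef2 == pytest.approx(
            np.mean(np.array(res.fold_coefs) ** 2), abs=1e-15
        )

    def test_monte_carlo_recovery(self):
        # y = 3x + 2 + N(0, 0.5), n = 200, k = 10
        rng = np.random.default_rng(123)
        x = rng.uniform(0, 2, size=200)
        y = 3 * x + 2 + rng.normal(0, 0.5, size=200)
        res = kfold_evaluate(x, y, k=10, seed=7)
        assert 0.4 < res.mean_rmse < 0.6
        se = 0.5 / np.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(res.slope - 3.0) < 3 * se

    def test_same_seed_identical(self, rng):
        x = rng.uniform(size=40)
        y = x + rng.normal(0, 0.1, size=40)
        a = kfold_evaluate(x, y, k=5, seed=21)
        b = kfold_evaluate(x, y, k=5, seed=21)
        assert a.fold_r2 == b.fold_r2
        assert a.mean_rmse == b.mean_rmse

    def test_full_data_refit_coefficients(self, rng):
        x = rng.uniform(size=40)
        y = 2 * x + 1 + rng.normal(0, 0.05, size=40)
        res = kfold_evaluate(x, y, k=4, seed=0)
        slope, intercept = normal_equations(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)


class TestRankIndices:
    def make_table(self, rng, n=50):
        lai = rng.uniform(0.5, 8, size=n)
        return pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(n)],
                "LAI": lai,
                "VI_signal": 0.1 * lai,               # exactly proportional
                "VI_noise": rng.normal(size=n),       # pure noise
                "Ene": rng.uniform(0.1, 1, size=n),
            }
        )

    def test_proportional_feature_ranks_first(self, rng):
        table = self.make_table(rng)
        results = rank_indices(table, k=5, seed=1)
        assert results[0].name == "VI_signal"
        assert results[0].mean_r2 == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_columns_tie_break_by_name(self, rng):
        table = self.make_table(rng)
        table["VI_copy"] = table["VI_signal"]
        results = rank_indices(table, k=5, seed=1)
        assert [r.name for r in results[:2]] == ["VI_copy", "VI_signal"]
        assert results[0].mean_r2 == results[1].mean_r2

    def test_requires_feature_columns(self):
        with pytest.raises(InputError):
            rank_indices(pd.DataFrame({"LAI": [1.0, 2.0, 3.0]}), k=2, seed=0)

    def test_requires_lai_column(self):
        with pytest.raises(InputError):
            rank_indices(pd.DataFrame({"VI_x": [1.0, 2.0, 3.0]}), k=2, seed=0)
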