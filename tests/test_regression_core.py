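import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from weantime import (
    DegenerateFitError,
    SingularDesignError,
    ValidationError,
    format_p,
    loo_species_prediction,
    ols_ancova,
    partial_correlation,
    predict_with_interval,
    rma_fit,
    sequential_partition,
)
from weantime.trait_data import TraitTable

from conftest import toy_frame


def random_design(seed: int, n: int | None = None, p: int | None = None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(8, 31))
    p = p or int(rng.integers(1, min(4, n - 2) + 1))
    df = pd.DataFrame({f"x{j}": rng.normal(size=n) for j in range(p)})
    beta = rng.normal(size=p)
    df["y"] = 1.0 + df.iloc[:, :p].to_numpy() @ beta + rng.normal(0, 0.5, n)
    return df, [f"x{j}" for j in range(p)]


class TestRma:
    def test_perfect_line_and_swap_symmetry(self):
        x = np.linspace(0, 5, 10)
        y = 2 * x + 1
        fit = rma_fit(x, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        swapped = rma_fit(y, x)
        assert swapped.slope == pytest.approx(1.0 / fit.slope)

    def test_slope_is_geometric_mean_of_directional_ols(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(0, 0.6, 20)
        fit = rma_fit(x, y)
        # brute-force OLS in both directions
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert abs(fit.slope) == pytest.approx(math.sqrt(abs(b_yx / b_xy)), rel=1e-10)
        assert math.copysign(1, fit.slope) == math.copysign(1, fit.r)
        assert fit.r_squared == pytest.approx(fit.r ** 2)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            rma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOlsAncova:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        """Coefficients agree with an explicit normal-equations solve."""
        df, predictors = random_design(seed)
        fit = ols_ancova(df, "y", predictors)
        X = np.column_stack([np.ones(len(df))] + [df[p] for p in predictors])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        got = np.array([fit.coefficients["intercept"]]
                       + [fit.coefficients[p] for p in predictors])
        np.testing.assert_allclose(got, beta, atol=1e-10, rtol=1e-8)
        # structural invariants
        assert fit.df_model + fit.df_residual + 1 == fit.n
        assert fit.adj_r_squared <= fit.r_squared
        assert abs(fit.residuals.sum()) < 1e-8 * max(1.0, np.abs(df["y"]).sum())

    def test_matches_statsmodels_inference(self):
        """F, R², p-values and Type III eta² agree with the statsmodels oracle."""
        import statsmodels.api as sm

        df, predictors = random_design(99, n=25, p=2)
        df["d"] = (df["x0"] + np.random.default_rng(1).normal(0, 1, len(df)) > 0).astype(float)
        df["y"] = df["y"] - 0.4 * df["d"]
        predictors = predictors + ["d"]
        fit = ols_ancova(df, "y", predictors[:2], ["d"])
        X = sm.add_constant(df[predictors])
        res = sm.OLS(df["y"], X).fit()
        assert fit.r_squared == pytest.approx(res.rsquared, rel=1e-10)
        assert fit.adj_r_squared == pytest.approx(res.rsquared_adj, rel=1e-10)
        assert fit.f_statistic == pytest.approx(res.fvalue, rel=1e-8)
        # printed F statistics are matched as computed statistics within 1%
        assert abs(fit.f_statistic - res.fvalue) <= 0.01 * res.fvalue
        for name in predictors:
            assert fit.coefficient_p_values[name] == pytest.approx(
                res.pvalues[name], rel=1e-8)
            # Type III: t² of the coefficient equals the drop-one-term F
            assert fit.term_f[name] == pytest.approx(res.tvalues[name] ** 2, rel=1e-8)
            ss_term = fit.term_f[name] * res.mse_resid
            assert fit.partial_eta_squared[name] == pytest.approx(
                ss_term / (ss_term + res.ssr), rel=1e-8)

    def test_dummy_validation_and_saturated_signal(self):
        df = toy_frame(10)
        table = TraitTable(df)
        frame = table.to_frame()
        frame["exact"] = 3.0 - 2.0 * frame["log_brain"]
        fit = ols_ancova(frame, "exact", ["log_brain"])
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)
        with pytest.raises(ValidationError, match="0/1"):
            ols_ancova(frame, "log_wean_pc", ["log_brain"], ["brain_mass_g"])

    def test_singular_design_raises(self):
        df, predictors = random_design(5, n=15, p=2)
        df["dup"] = df["x0"] * 2.0
        with pytest.raises(SingularDesignError):
            ols_ancova(df, "y", predictors + ["dup"])


class TestSequentialPartition:
    def test_single_predictor_equals_its_r_squared(self):
        df, predictors = random_design(7, n=20, p=1)
        part = sequential_partition(df, "y", predictors)
        fit = ols_ancova(df, "y", predictors)
        assert part.increments[0] == pytest.approx(fit.r_squared * 100, abs=1e-8)

    def test_orthogonal_predictors_order_invariant(self):
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": x1, "x2": x2,
                           "y": 0.5 * x1 - 0.3 * x2 + rng.normal(0, 0.2, n)})
        a = sequential_partition(df, "y", ["x1", "x2"])
        b = sequential_partition(df, "y", ["x2", "x1"])
        assert a.increments[0] == pytest.approx(b.increments[1], abs=1e-8)
        assert a.total == pytest.approx(b.total, abs=1e-10)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_additivity_and_monotonicity(self, seed):
        """Increments are >= 0, sum to the full-model R²·100 within 1e-8."""
        df, predictors = random_design(seed)
        part = sequential_partition(df, "y", predictors)
        fit = ols_ancova(df, "y", predictors)
        assert sum(part.increments) == pytest.approx(part.total, abs=1e-8)
        assert part.total == pytest.approx(fit.r_squared * 100, abs=1e-8)
        assert all(inc >= -1e-10 for inc in part.increments)


class TestPartialCorrelation:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(12)
        c = rng.normal(size=30)
        x = 0.8 * c + rng.normal(0, 0.7, 30)
        y = 0.5 * c + 0.4 * x + rng.normal(0, 0.7, 30)
        r, p = partial_correlation(x, y, c)
        rxy = np.corrcoef(x, y)[0, 1]
        rxc = np.corrcoef(x, c)[0, 1]
        ryc = np.corrcoef(y, c)[0, 1]
        expect = (rxy - rxc * ryc) / math.sqrt((1 - rxc ** 2) * (1 - ryc ** 2))
        assert r == pytest.approx(expect, abs=1e-10)
        assert 0 <= p <= 1

    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = 0.6 * x + rng.normal(0, 0.8, 400)
        c = rng.normal(size=400)
        r, _ = partial_correlation(x, y, c)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_collinear_with_control_is_degenerate(self):
        c = np.linspace(0, 1, 10)
        with pytest.raises(DegenerateFitError):
            partial_correlation(c, np.random.default_rng(0).normal(size=10), c)


class TestPrediction:
    def test_interval_collapses_at_tiny_level_and_zero_residuals(self):
        df, predictors = random_design(21, n=12, p=1)
        fit = ols_ancova(df, "y", predictors)
        point = {"x0": 0.3}
        wide = predict_with_interval(fit, point, level=0.90)
        narrow = predict_with_interval(fit, point, level=1e-9)
        assert wide.interval_low <= wide.point <= wide.interval_high
        assert (narrow.interval_high - narrow.interval_low) < 1e-6
        # exact fit -> zero-width interval at any level
        df["exact"] = 2.0 + 3.0 * df["x0"]
        efit = ols_ancova(df, "exact", predictors)
        pred = predict_with_interval(efit, point, level=0.99)
        assert pred.interval_high - pred.interval_low == pytest.approx(0.0, abs=1e-8)
        assert pred.point_days == pytest.approx(10 ** pred.point)

    def test_extrapolation_flag(self):
        df, predictors = random_design(22, n=12, p=1)
        fit = ols_ancova(df, "y", predictors)
        inside = predict_with_interval(fit, {"x0": float(df["x0"].median())})
        outside = predict_with_interval(fit, {"x0": float(df["x0"].max() + 10)})
        assert not inside.extrapolation
        assert outside.extrapolation

    def test_loo_perfect_line_predicts_held_out_point(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({
            "species": ["a", "b", "c", "d"],
            "order": ["o"] * 4,
            "brain_mass_g": 10 ** x,
            "body_mass_g": [100.0] * 4,
            "gestation_d": [10.0] * 4,
            "wean_postnatal_d": 10 ** (1.0 + 0.5 * x) - 10.0,
            "limb": ["plantigrade"] * 4,
            "diet": ["carnivore"] * 4,
        })
        table = TraitTable(df)
        pred, fit = loo_species_prediction(table, "c", continuous=("log_brain",),
                                           dummies=())
        held_out = table.to_frame().set_index("species").loc["c", "log_wean_pc"]
        assert pred.point == pytest.approx(held_out, abs=1e-9)

    def test_empirical_coverage_at_n67(self):
        """90% prediction intervals cover a fresh observation ~90% of the time."""
        rng = np.random.default_rng(2024)
        n, sigma = 67, 0.15
        x = rng.normal(1.5, 1.1, n)
        lb = (rng.random(n) < 0.43).astype(float)
        dp = (rng.random(n) < 0.75).astype(float)
        X = np.column_stack([np.ones(n), x, lb, dp])
        beta = np.array([2.1, 0.3, -0.25, 0.2])
        x0 = {"x": 3.12, "lb": 0.0, "dp": 0.0}
        truth0 = beta @ np.array([1.0, 3.12, 0.0, 0.0])
        hits = 0
        reps = 2000
        df = pd.DataFrame({"x": x, "lb": lb, "dp": dp})
        for _ in range(reps):
            df["y"] = X @ beta + rng.normal(0, sigma, n)
            fit = ols_ancova(df, "y", ["x"], ["lb", "dp"])
            pred = predict_with_interval(fit, x0, level=0.90)
            new_obs = truth0 + rng.normal(0, sigma)
            hits += pred.interval_low <= new_obs <= pred.interval_high
        coverage = hits / reps
        assert abs(coverage - 0.90) <= 3 * math.sqrt(0.9 * 0.1 / reps)


def test_p_value_formatting_convention():
    assert format_p(2e-5) == "<.0001"
    assert format_p(0.0123) == "0.0123"
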