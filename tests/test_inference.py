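"""OLS, backward elimination, Shapiro-Wilk, RMA regression."""

import numpy as np
import pandas as pd
import pytest

from pollenrisk.inference import (backward_eliminate, ols_fit, rma_regression,
                                  shapiro_wilk, simple_regression)


def _df(**cols):
    return pd.DataFrame(cols)


class TestOls:
    def test_exact_fit_recovers_coefficients(self):
        x = np.arange(10.0)
        res = ols_fit(3 + 2 * x, _df(x1=x))
        assert res.term("x1")[0] == pytest.approx(2.0)
        assert res.intercept == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=200)
        y = x + rng.normal(scale=0.7, size=200)
        res = ols_fit(y, _df(x1=x))
        beta, _ = res.term("x1")
        assert abs(beta - 1.0) < 3 * res.std_errors[0]

    def test_null_model_p_uniformity(self):
        # overall F-test p should be uniform when y is independent of X
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            X = _df(a=rng.normal(size=100), b=rng.normal(size=100))
            pvals.append(ols_fit(rng.normal(size=100), X).model_p)
        pvals = np.asarray(pvals)
        assert 0.02 <= (pvals <= 0.05).mean() <= 0.09
        assert abs(np.mean(pvals) - 0.5) < 0.08

    def test_collinear_design_rejected_with_names(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="near-dependency"):
            ols_fit(x, _df(a=x, b=2 * x))

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError, match="n > p"):
            ols_fit([1.0, 2.0, 3.0], _df(a=[1, 2, 3], b=[3, 1, 2]))


class TestBackwardElimination:
    def test_dominant_effect_survives_noise_predictors(self):
        rng = np.random.default_rng(7)
        X = _df(x1=rng.normal(size=100), n1=rng.normal(size=100),
                n2=rng.normal(size=100), n3=rng.normal(size=100))
        y = 2 * X["x1"] + rng.normal(size=100)
        res = backward_eliminate(y, X)
        assert res.predictors == ("x1",)
        assert {t for t, _ in res.elimination_trace} == {"n1", "n2", "n3"}
        assert all(p > 0.05 for _, p in res.elimination_trace)

    def test_pure_noise_ends_intercept_only(self):
        rng = np.random.default_rng(3)
        X = _df(**{f"n{i}": rng.normal(size=100) for i in range(4)})
        res = backward_eliminate(rng.normal(size=100), X)
        assert res.predictors == ()
        assert len(res.elimination_trace) == 4

    def test_exact_joint_model_drops_nothing(self):
        rng = np.random.default_rng(5)
        X = _df(a=rng.normal(size=30), b=rng.normal(size=30))
        y = X["a"] - X["b"]
        res = backward_eliminate(y, X)
        assert set(res.predictors) == {"a", "b"}
        assert res.elimination_trace == ()

    def test_result_is_fixed_point(self):
        rng = np.random.default_rng(11)
        X = _df(a=rng.normal(size=60), b=rng.normal(size=60),
                c=rng.normal(size=60))
        y = 1.5 * X["a"] + 0.1 * X["b"] + rng.normal(size=60)
        res = backward_eliminate(y, X)
        again = backward_eliminate(y, X[list(res.predictors)])
        assert again.terms == res.terms
        assert again.elimination_trace == ()

    def test_retained_terms_all_significant(self):
        rng = np.random.default_rng(13)
        X = _df(**{f"v{i}": rng.normal(size=40) for i in range(4)})
        y = X["v0"] + 0.5 * X["v2"] + rng.normal(size=40)
        res = backward_eliminate(y, X, alpha=0.05)
        assert all(p <= 0.05 for _, _, p in res.terms)

    def test_dropping_a_retained_predictor_lowers_r_squared(self):
        rng = np.random.default_rng(17)
        X = _df(a=rng.normal(size=50), b=rng.normal(size=50))
        y = X["a"] + X["b"] + rng.normal(scale=0.5, size=50)
        full = ols_fit(y, X)
        reduced = ols_fit(y, X[["a"]])
        assert reduced.r_squared < full.r_squared


class TestShapiroWilk:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(1)
        w, p = shapiro_wilk(rng.normal(size=50))
        assert p > 0.05

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(1)
        w, p = shapiro_wilk(rng.exponential(size=50))
        assert p < 0.01

    def test_tiny_symmetric_sample_near_ideal(self):
        w, _ = shapiro_wilk([-1.0, 0.0, 1.0])
        assert w > 0.99

    @pytest.mark.parametrize("bad", [[1.0, 1.0, 1.0], [1.0, 2.0]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            shapiro_wilk(bad)


class TestRma:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = rma_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        fwd = rma_regression(x, y)
        back = rma_regression(y, x)
        assert fwd.slope * back.slope == pytest.approx(1.0)

    def test_slope_magnitude_is_ols_over_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        y = 0.8 * x + rng.normal(size=80)
        rma = rma_regression(x, y)
        ols_beta = ols_fit(y, _df(x=x)).term("x")[0]
        assert abs(rma.r) > 0.1
        assert abs(rma.slope) == pytest.approx(abs(ols_beta / rma.r), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rma_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_permutation_p_is_seeded_and_agrees_with_t(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        a = rma_regression(x, y, n_perm=999, seed=5)
        b = rma_regression(x, y, n_perm=999, seed=5)
        assert a.p_value == b.p_value
        t_based = rma_regression(x, y).p_value
        assert abs(a.p_value - t_based) < 0.02 + t_based


class TestSimpleRegression:
    def test_exact_line_significant(self):
        x = np.arange(12.0)
        res = simple_regression(x, 4 - 3 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.term("x")[0] == pytest.approx(-3.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_regression(np.ones(10), np.arange(10.0))
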