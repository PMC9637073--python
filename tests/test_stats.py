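"""Descriptive statistics, correlation, OLS and LASSO stages."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from regenpath import stats as st


class TestDescribe:
    def test_constant_vector(self):
        d = st.describe([5, 5, 5, 5])
        assert (d.mean, d.variance) == (5.0, 0.0)
        assert np.isnan(d.skewness) and np.isnan(d.kurtosis)

    def test_hand_computed_moments(self):
        d = st.describe([1, 2, 3, 4, 5])
        assert d.mean == pytest.approx(3.0)
        assert d.variance == pytest.approx(2.5)  # n-1 divisor
        assert d.skewness == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_sample_has_null_shape_moments(self, rng):
        x = rng.standard_normal(200_000)
        d = st.describe(x)
        # Monte-Carlo error ~ sqrt(6/n) and sqrt(24/n)
        assert abs(d.skewness) < 4 * np.sqrt(6 / x.size)
        assert abs(d.kurtosis) < 4 * np.sqrt(24 / x.size)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.describe([])


class TestPearsonMatrix:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"x": x, "y": 2 * x + 1})
        res = st.pearson_matrix(data)
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.sig_01.loc["x", "y"]

    def test_hand_computed_five_point_pair(self):
        # sum of cross-products gives cov -2, sd^2 = 2.5 each: r = -0.8
        data = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [5, 3, 4, 1, 2]})
        res = st.pearson_matrix(data)
        assert res.r.loc["x", "y"] == pytest.approx(-0.8)
        assert res.p.loc["x", "y"] == pytest.approx(0.104088, abs=1e-5)
        assert not res.sig_05.loc["x", "y"]

    def test_independent_columns_average_to_zero(self, rng):
        rs = []
        for _ in range(200):
            data = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
            rs.append(st.pearson_matrix(data).r.loc["a", "b"])
        assert abs(np.mean(rs)) < 3 / np.sqrt(29 * 200)

    def test_affine_rescaling_invariance(self, rng):
        data = pd.DataFrame(rng.standard_normal((25, 3)), columns=list("abc"))
        scaled = data.copy()
        scaled["b"] = 100.0 * scaled["b"] - 7.0
        r1 = st.pearson_matrix(data).r
        r2 = st.pearson_matrix(scaled).r
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_zero_variance_variable_reported_missing(self):
        data = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        res = st.pearson_matrix(data)
        assert np.isnan(res.r.loc["x", "c"])


class TestOLS:
    def test_identity_fit(self):
        x = np.arange(8.0)
        fit = st.ols_fit(x, pd.DataFrame({"x": x}))
        assert fit.slopes["x"] == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_normal_equations(self):
        fit = st.ols_fit([1, 2, 4], pd.DataFrame({"x": [0, 1, 2]}))
        assert fit.slopes["x"] == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(5.0 / 6.0)

    def test_r_squared_equals_squared_pearson_r(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        data = pd.DataFrame({"x": x, "y": y})
        fit = st.ols_fit(y, data[["x"]])
        r = st.pearson_matrix(data).r.loc["x", "y"]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError):
            st.ols_fit(rng.standard_normal(20), X)


class TestOLSFromSummary:
    def test_published_summary_inputs(self):
        # regeneration efficiency on Cu(II): slope/intercept from the summary
        # tables differ from the printed equation, whose coefficients appear
        # transposed; the summaries are self-consistent with R^2 = r^2.
        fit = st.ols_from_summary(5.427, 2.556, 12.787, 2.752, 0.807, 37)
        assert fit.r_squared == pytest.approx(0.6512, abs=5e-4)
        assert fit.slopes["x"] == pytest.approx(0.3744, abs=5e-4)
        assert fit.intercept == pytest.approx(0.5242, abs=5e-4)

    def test_zero_correlation(self):
        fit = st.ols_from_summary(2.0, 7.0, 4.0, 9.0, 0.0, 20)
        assert fit.slopes["x"] == 0.0
        assert fit.intercept == pytest.approx(7.0)
        assert fit.r_squared == 0.0

    def test_agrees_with_raw_data_fit(self, rng):
        x = rng.standard_normal(50) * 3 + 1
        y = 0.7 * x + rng.standard_normal(50)
        raw = st.ols_fit(y, pd.DataFrame({"x": x}))
        r = float(np.corrcoef(x, y)[0, 1])
        summ = st.ols_from_summary(x.mean(), y.mean(), x.var(ddof=1), y.var(ddof=1), r, 50)
        assert summ.slopes["x"] == pytest.approx(raw.slopes["x"], abs=1e-10)
        assert summ.intercept == pytest.approx(raw.intercept, abs=1e-10)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            st.ols_from_summary(1.0, 2.0, 0.0, 1.0, 0.5, 10)


def orthonormal_design(n=64, k=4):
    X = hadamard(n)[:, 1:k + 1].astype(float)  # X'X = n I
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])


class TestLasso:
    def test_lambda_zero_reproduces_ols(self, rng):
        X = orthonormal_design()
        y = X.to_numpy() @ [2.0, -1.0, 0.5, 0.0] + rng.normal(0, 0.5, len(X))
        lf = st.lasso_fit(y, X, lambda_grid=[0.0], standardize=False)
        ols = st.ols_fit(y, X)
        for c in X.columns:
            assert lf.slopes[c] == pytest.approx(ols.slopes[c], abs=1e-6)

    def test_large_lambda_shrinks_all_slopes_to_zero(self, rng):
        X = orthonormal_design()
        y = X.to_numpy() @ [2.0, -1.0, 0.5, 0.0] + rng.normal(0, 0.5, len(X))
        lam_max = np.max(np.abs(X.to_numpy().T @ (y - y.mean()))) / len(y)
        lf = st.lasso_fit(y, X, lambda_grid=[lam_max * 1.01], standardize=False)
        assert all(b == 0.0 for b in lf.slopes.values())

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        X = orthonormal_design()
        Xv = X.to_numpy()
        y = Xv @ [2.0, -1.0, 0.5, 0.0] + rng.normal(0, 0.5, len(X))
        lam = 0.3
        lf = st.lasso_fit(y, X, lambda_grid=[lam], standardize=False)
        b_ols = Xv.T @ (y - y.mean()) / len(y)
        soft = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        assert np.allclose(list(lf.slopes.values()), soft, atol=1e-8)

    def test_cv_is_reproducible_given_seed(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
        y = X["a"] * 2 - X["c"] + rng.standard_normal(60)
        f1 = st.lasso_fit(y, X, seed=11)
        f2 = st.lasso_fit(y, X, seed=11)
        assert f1.optimal_lambda == f2.optimal_lambda
        assert f1.slopes == f2.slopes
        assert np.array_equal(f1.fold_assignments, f2.fold_assignments)

    def test_constant_predictor_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(30), "c": np.ones(30)})
        y = X["a"] + rng.standard_normal(30)
        with pytest.warns(UserWarning, match="constant"):
            lf = st.lasso_fit(y, X, k_folds=5)
        assert lf.dropped == ["c"]
        assert "c" not in lf.slopes
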