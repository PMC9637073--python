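"""Descriptive statistics, Pearson correlation, OLS and cross-validated LASSO.

These are the pre-path-model stages of the analysis: per-variable summaries,
the correlation screen, the single-predictor regression of regeneration
efficiency on medium composition, and LASSO variable selection among the
medium and methylation covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold


@dataclass
class DescriptiveStats:
    n: int
    mean: float
    variance: float  # unbiased, n-1 divisor
    skewness: float  # adjusted Fisher-Pearson
    kurtosis: float  # adjusted excess

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def describe(values) -> DescriptiveStats:
    """Mean, unbiased variance, and small-sample-adjusted skewness/excess kurtosis.

    Skewness uses the adjusted Fisher–Pearson form g1·√(n(n−1))/(n−2) (n ≥ 3);
    kurtosis is the adjusted excess form (n ≥ 4).  With fewer observations, or
    for a constant input, the undefined moments are reported as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("describe() needs a non-empty 1-d numeric vector")
    n = x.size
    mean = float(x.mean())
    variance = float(x.var(ddof=1)) if n > 1 else 0.0
    if n >= 3 and variance > 0:
        skew = float(sps.skew(x, bias=False))
    else:
        skew = float("nan")
    if n >= 4 and variance > 0:
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    else:
        kurt = float("nan")
    return DescriptiveStats(n=n, mean=mean, variance=variance, skewness=skew, kurtosis=kurt)


def describe_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-column descriptives, one row per variable."""
    return pd.DataFrame(
        {col: describe(data[col].to_numpy()).as_dict() for col in data.columns}
    ).T


@dataclass
class CorrelationResult:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    sig_05: pd.DataFrame
    sig_01: pd.DataFrame


def pearson_matrix(data: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson r with two-sided t-test p-values (df = n−2).

    Zero-variance variables get NaN correlations (and p-values) against every
    other variable; the diagonal is r = 1, p = 0.
    """
    cols = list(data.columns)
    p_n = len(cols)
    r = np.eye(p_n)
    p = np.zeros((p_n, p_n))
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    for i in range(p_n):
        for j in range(i + 1, p_n):
            if sd[i] == 0 or sd[j] == 0:
                rij, pij = np.nan, np.nan
            else:
                pair = np.column_stack((x[:, i], x[:, j]))
                pair = pair[~np.isnan(pair).any(axis=1)]
                if pair.shape[0] < 3:
                    raise ValueError(
                        f"need >=3 complete observations for pair ({cols[i]}, {cols[j]})"
                    )
                res = sps.pearsonr(pair[:, 0], pair[:, 1])
                rij, pij = float(res.statistic), float(res.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationResult(
        variables=cols,
        r=rdf,
        p=pdf,
        sig_05=pdf.le(0.05) & ~np.eye(p_n, dtype=bool),
        sig_01=pdf.le(0.01) & ~np.eye(p_n, dtype=bool),
    )


@dataclass
class RegressionFit:
    intercept: float
    slopes: dict[str, float]
    r_squared: float
    residual_variance: float
    n: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for name, b in self.slopes.items():
            out = out + b * X[name].to_numpy(dtype=float)
        return out


def ols_fit(y, X: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares of y on the predictor table (with intercept)."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > #predictors + 1 (n={n}, predictors={k})")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    return RegressionFit(
        intercept=float(res.params[0]),
        slopes={name: float(b) for name, b in zip(X.columns, res.params[1:])},
        r_squared=float(res.rsquared),
        residual_variance=float(res.mse_resid),
        n=n,
    )


def ols_from_summary(
    mean_x: float, mean_y: float, var_x: float, var_y: float, r: float, n: int
) -> RegressionFit:
    """Single-predictor OLS reconstructed from summary statistics alone.

    slope = r·√(var_y/var_x), intercept = mean_y − slope·mean_x, R² = r².
    Useful when only published means/variances/correlations are available.
    """
    if var_x <= 0:
        raise ValueError("var_x must be positive")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    slope = r * np.sqrt(var_y / var_x)
    intercept = mean_y - slope * mean_x
    return RegressionFit(
        intercept=float(intercept),
        slopes={"x": float(slope)},
        r_squared=float(r**2),
        residual_variance=float(var_y * (1 - r**2)),
        n=n,
    )


@dataclass
class LassoFit:
    lambda_grid: np.ndarray
    optimal_lambda: float
    intercept: float
    slopes: dict[str, float]  # original scale
    cv_mse: np.ndarray  # mean CV squared error per lambda
    fold_assignments: np.ndarray
    seed: int
    dropped: list[str] = field(default_factory=list)


def _lasso_path_coefs(Xs: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    coefs = np.empty((len(alphas), Xs.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # alpha=0 convergence warning
        for i, a in enumerate(alphas):
            model = Lasso(alpha=a, fit_intercept=False, max_iter=200_000, tol=1e-12)
            model.fit(Xs, yc)
            coefs[i] = model.coef_
    return coefs


def lasso_fit(
    y,
    X: pd.DataFrame,
    lambda_grid=None,
    k_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> LassoFit:
    """L1-penalised regression with k-fold cross-validated penalty selection.

    Minimises (1/2n)·‖y − b₀ − Xb‖² + λ·Σ|bⱼ| by coordinate descent.
    Predictors are standardized internally (population SD) and coefficients
    back-transformed to the original scale; constant predictors are dropped
    with a warning.  The default grid is 100 log-spaced values from λ_max
    (the smallest λ with all slopes zero) down to 1e-4·λ_max.  The optimal λ
    minimises the mean CV squared prediction error; with a fixed seed the fold
    split, and hence the result, is bit-reproducible.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not (n >= k_folds >= 2):
        raise ValueError(f"need n >= k_folds >= 2 (n={n}, k_folds={k_folds})")

    dropped = [c for c in X.columns if np.std(X[c].to_numpy(dtype=float)) == 0]
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    mu_x, mu_y = Xv.mean(axis=0), y.mean()
    if standardize:
        sd_x = Xv.std(axis=0)
    else:
        sd_x = np.ones(Xv.shape[1])
    Xs = (Xv - mu_x) / sd_x
    yc = y - mu_y

    if lambda_grid is None:
        lam_max = np.max(np.abs(Xs.T @ yc)) / n
        lambda_grid = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), 100)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    cv_sse = np.zeros(len(lambda_grid))
    for fold, (train, test) in enumerate(kf.split(Xs)):
        folds[test] = fold
        coefs = _lasso_path_coefs(Xs[train], yc[train], lambda_grid)
        pred = Xs[test] @ coefs.T  # (n_test, n_lambda)
        cv_sse += ((yc[test, None] - pred) ** 2).sum(axis=0)
    cv_mse = cv_sse / n
    best = int(np.argmin(cv_mse))
    opt_lambda = float(lambda_grid[best])

    coef_std = _lasso_path_coefs(Xs, yc, np.array([opt_lambda]))[0]
    slopes = coef_std / sd_x
    intercept = mu_y - float(slopes @ mu_x)
    return LassoFit(
        lambda_grid=lambda_grid,
        optimal_lambda=opt_lambda,
        intercept=intercept,
        slopes={name: float(b) for name, b in zip(names, slopes)},
        cv_mse=cv_mse,
        fold_assignments=folds,
        seed=seed,
        dropped=dropped,
    )
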