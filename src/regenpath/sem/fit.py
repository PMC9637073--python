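"""Maximum-likelihood covariance-structure fitting for path models.

The fitting function is the normal-theory ML discrepancy

    F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

minimised over the free parameters by a damped-Hessian (Levenberg–Marquardt)
iteration with the expected information 0.5·tr(Σ⁻¹ ∂ᵢΣ Σ⁻¹ ∂ⱼΣ) as the
curvature matrix.  χ² = (N−1)·F_min; standard errors come from the inverse of
the expected information of the log-likelihood, 0.5·(N−1)·tr(Σ⁻¹∂ᵢΣ Σ⁻¹∂ⱼΣ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PathModel, count_df


class FitError(RuntimeError):
    pass


@dataclass
class SampleMoments:
    """Sample covariance matrix S with its sample size and variable names."""

    S: np.ndarray
    n: int
    variables: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.variables)
        if self.S.shape != (p, p):
            raise ValueError(f"S has shape {self.S.shape}, expected ({p}, {p})")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S is not symmetric")
        if np.any(np.linalg.eigvalsh(self.S) <= 0):
            raise ValueError("S is not positive definite")
        if self.n < 2:
            raise ValueError("need n >= 2")

    @classmethod
    def from_data(cls, data: pd.DataFrame, ddof: int = 1) -> "SampleMoments":
        x = data.to_numpy(dtype=float)
        return cls(
            S=np.cov(x, rowvar=False, ddof=ddof),
            n=x.shape[0],
            variables=list(data.columns),
        )

    def reordered(self, variables: list[str]) -> "SampleMoments":
        idx = [self.variables.index(v) for v in variables]
        return SampleMoments(S=self.S[np.ix_(idx, idx)], n=self.n, variables=list(variables))


def _theta_to_matrices(theta: np.ndarray, model: PathModel) -> tuple[np.ndarray, np.ndarray]:
    p = model.p
    pos = {v: i for i, v in enumerate(model.variables)}
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    k = 0
    for e in model.paths:
        B[pos[e.dst], pos[e.src]] = theta[k]
        k += 1
    for v in model.exogenous:
        Psi[pos[v], pos[v]] = theta[k]
        k += 1
    for c in model.covariances:
        Psi[pos[c.a], pos[c.b]] = Psi[pos[c.b], pos[c.a]] = theta[k]
        k += 1
    for v in model.endogenous:
        Psi[pos[v], pos[v]] = theta[k]
        k += 1
    return B, Psi


def implied_covariance(theta: np.ndarray, model: PathModel) -> np.ndarray:
    """Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ for the parameter vector θ."""
    B, Psi = _theta_to_matrices(np.asarray(theta, dtype=float), model)
    I = np.eye(model.p)
    try:
        A = np.linalg.inv(I - B)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"(I - B) is singular for theta={theta!r}") from exc
    return A @ Psi @ A.T


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray, p: int | None = None) -> float:
    """Normal-theory ML discrepancy F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p ≥ 0."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if p is None:
        p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise FitError("S and Sigma must be positive definite")
    return float(logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def chi_square_p(chi2: float, df: int) -> float:
    """Upper-tail χ² probability."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    return float(sps.chi2.sf(chi2, df))


@dataclass
class FitOptions:
    gtol: float = 1e-10
    max_iter: int = 500
    restarts: int = 5
    seed: int = 0
    chi2_multiplier: str = "n-1"  # or "n"


@dataclass
class SEMFit:
    model: PathModel
    moments: SampleMoments
    labels: list[str]
    estimates: np.ndarray
    se: np.ndarray
    critical_ratio: np.ndarray
    standardized: np.ndarray
    sigma: np.ndarray
    f_min: float
    chi_square: float
    df: int
    p_value: float
    converged: bool
    iterations: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.moments.n

    def estimate(self, label: str) -> float:
        return float(self.estimates[self.labels.index(label)])

    def summary(self) -> pd.DataFrame:
        """Per-parameter table: estimate, SE, critical ratio, standardized."""
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "se": self.se,
                "critical_ratio": self.critical_ratio,
                "standardized": self.standardized,
            },
            index=self.labels,
        )


def _derivative_matrices(model: PathModel) -> list[tuple[str, tuple]]:
    """Structural description of ∂B/∂θᵢ and ∂Ψ/∂θᵢ for each free parameter."""
    pos = {v: i for i, v in enumerate(model.variables)}
    out: list[tuple[str, tuple]] = []
    for e in model.paths:
        out.append(("B", (pos[e.dst], pos[e.src])))
    for v in model.exogenous:
        out.append(("Psi", (pos[v], pos[v])))
    for c in model.covariances:
        out.append(("Psi", (pos[c.a], pos[c.b])))
    for v in model.endogenous:
        out.append(("Psi", (pos[v], pos[v])))
    return out


def _grad_hess(theta: np.ndarray, model: PathModel, S: np.ndarray):
    """F, gradient and expected-information curvature at θ."""
    B, Psi = _theta_to_matrices(theta, model)
    p = model.p
    I = np.eye(p)
    A = np.linalg.inv(I - B)
    Sigma = A @ Psi @ A.T
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return np.inf, None, None, Sigma
    Sigma_inv = np.linalg.inv(Sigma)
    F = ml_discrepancy(S, Sigma, p)

    derivs = []
    structure = _derivative_matrices(model)
    for kind, idx in structure:
        if kind == "B":
            dB = np.zeros((p, p))
            dB[idx] = 1.0
            M = A @ dB @ Sigma
            dSigma = M + M.T
        else:
            dPsi = np.zeros((p, p))
            i, j = idx
            dPsi[i, j] = 1.0
            if i != j:
                dPsi[j, i] = 1.0
            dSigma = A @ dPsi @ A.T
        derivs.append(dSigma)

    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    q = len(derivs)
    g = np.array([np.sum(W * d) for d in derivs])  # tr(W d), W symmetric
    pre = [Sigma_inv @ d for d in derivs]
    H = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            H[i, j] = H[j, i] = 0.5 * np.sum(pre[i] * pre[j].T)
    return F, g, H, Sigma


def _start_values(model: PathModel, S: np.ndarray, jitter: np.random.Generator | None = None):
    pos = {v: i for i, v in enumerate(model.variables)}
    theta = []
    for _ in model.paths:
        theta.append(0.0)
    for v in model.exogenous:
        theta.append(S[pos[v], pos[v]])
    for c in model.covariances:
        theta.append(S[pos[c.a], pos[c.b]])
    for v in model.endogenous:
        theta.append(0.5 * S[pos[v], pos[v]])
    theta = np.asarray(theta, dtype=float)
    if jitter is not None:
        q = len(theta)
        scale = np.where(theta == 0, 0.1, np.abs(theta) * 0.3)
        theta = theta + jitter.normal(0.0, scale, size=q)
        # keep variance start values positive
        n_paths = len(model.paths)
        k = n_paths
        for v in model.exogenous:
            theta[k] = max(theta[k], 0.05 * S[pos[v], pos[v]])
            k += 1
        k += len(model.covariances)
        for v in model.endogenous:
            theta[k] = max(theta[k], 0.05 * S[pos[v], pos[v]])
            k += 1
    return theta


def _lm_minimize(model: PathModel, S: np.ndarray, theta0: np.ndarray, opts: FitOptions):
    """Damped expected-information (Levenberg–Marquardt) descent on F."""
    theta = theta0.copy()
    F, g, H, _ = _grad_hess(theta, model, S)
    if not np.isfinite(F):
        return theta, np.inf, False, 0

    def decrement(g, H):
        # Newton decrement 0.5 g' H^-1 g: the expected remaining decrease in F.
        # Scale-invariant, so one tolerance covers path parameters and the
        # very differently scaled variance parameters alike.
        try:
            return float(0.5 * g @ np.linalg.solve(H, g))
        except np.linalg.LinAlgError:
            return float(0.5 * g @ np.linalg.lstsq(H, g, rcond=None)[0])

    mu, nu = 1e-3, 2.0
    it = 0
    converged = False
    for it in range(1, opts.max_iter + 1):
        if abs(decrement(g, H)) < opts.gtol:
            converged = True
            break
        # Marquardt diagonal scaling keeps the damping meaningful across the
        # very different natural scales of path and variance parameters.
        D = np.maximum(np.diag(H), 1e-12)
        try:
            delta = np.linalg.solve(H + mu * np.diag(D), -g)
        except np.linalg.LinAlgError:
            mu = min(mu * nu, 1e14)
            nu = min(nu * 2, 1e8)
            continue
        F_new, g_new, H_new, _ = _grad_hess(theta + delta, model, S)
        predicted = 0.5 * delta @ (mu * D * delta - g)
        if np.isfinite(F_new) and F_new <= F and predicted > 0:
            rho = (F - F_new) / predicted
            stalled = (F - F_new) < 1e-16 * max(abs(F), 1.0)
            theta = theta + delta
            F, g, H = F_new, g_new, H_new
            mu *= max(1.0 / 3.0, 1.0 - (2.0 * rho - 1.0) ** 3)
            mu = max(mu, 1e-16)
            nu = 2.0
            if stalled:
                converged = abs(decrement(g, H)) < max(opts.gtol, 1e-9)
                break
        else:
            mu = min(mu * nu, 1e14)
            nu = min(nu * 2, 1e8)
            if mu >= 1e14:
                break
    else:
        it = opts.max_iter
    if not converged and abs(decrement(g, H)) < opts.gtol:
        converged = True
    if converged:
        theta, F = _newton_polish(theta, F, model, S)
    return theta, F, converged, it


def _newton_polish(theta, F, model, S):
    """Quasi-Newton refinement from the damped-iteration solution.

    The expected information used for the main iteration can overstate the
    curvature of F when the model does not fit exactly, leaving the solution
    a few 1e-6 short of the optimum; a short BFGS run on the analytic
    gradient closes that gap.  The polished point is kept only if it does not
    increase F.
    """
    from scipy import optimize

    def fun(t):
        out = _grad_hess(t, model, S)
        if not np.isfinite(out[0]):
            return 1e10, np.zeros_like(t)
        return out[0], out[1]

    res = optimize.minimize(
        fun, theta, jac=True, method="BFGS",
        options={"gtol": 1e-12, "maxiter": 200},
    )
    if np.isfinite(res.fun) and res.fun <= F + 1e-14 * max(abs(F), 1.0):
        return res.x, float(min(F, res.fun))
    return theta, F


def fit_ml(
    model: PathModel,
    moments: SampleMoments,
    options: FitOptions | None = None,
) -> SEMFit:
    """Fit a path model to sample moments by maximum likelihood.

    Starts from zero paths with Ψ initialised from S (exogenous block as
    observed, residuals at half the sample variances); on non-convergence,
    up to ``options.restarts`` jittered restarts with seeded perturbations.
    Non-convergence is flagged on the returned fit, never silently ignored;
    a negative fitted variance attaches a Heywood-case warning.
    """
    opts = options or FitOptions()
    df = count_df(model)
    moments = moments.reordered(model.variables)
    S, N = moments.S, moments.n

    warns: list[str] = []
    rng = np.random.default_rng(opts.seed)
    best = None
    for attempt in range(opts.restarts + 1):
        theta0 = _start_values(model, S, jitter=None if attempt == 0 else rng)
        theta, F, converged, it = _lm_minimize(model, S, theta0, opts)
        if best is None or (converged and not best[2]) or (
            converged == best[2] and F < best[1]
        ):
            best = (theta, F, converged, it)
        if converged:
            break
    theta, F, converged, iterations = best
    if not converged:
        warns.append(
            f"non-convergence after {opts.restarts + 1} starts "
            f"(best F={F:.6g}); estimates are the best point found"
        )

    F_at, g, H, Sigma = _grad_hess(theta, model, S)
    mult = (N - 1) if opts.chi2_multiplier == "n-1" else N
    chi2 = max(mult * F, 0.0)
    p_value = chi_square_p(chi2, df) if df >= 1 else float("nan")

    # standard errors from the expected information of the log-likelihood
    info = mult * H
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
        warns.append("information matrix singular; standard errors unavailable")
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.where(se > 0, theta / se, np.nan)

    # Heywood screen: variance parameters must be positive at a valid solution
    labels = model.parameter_labels
    for lab, val in zip(labels, theta):
        if (lab.startswith("var_") or lab.startswith("resid_")) and val <= 0:
            warns.append(f"Heywood case: variance parameter {lab} = {val:.6g} <= 0")

    # standardization with model-implied standard deviations
    sd = np.sqrt(np.diag(Sigma))
    pos = {v: i for i, v in enumerate(model.variables)}
    std = np.full(len(theta), np.nan)
    k = 0
    for e in model.paths:
        std[k] = theta[k] * sd[pos[e.src]] / sd[pos[e.dst]]
        k += 1
    k += len(model.exogenous)
    for c in model.covariances:
        std[k] = theta[k] / (sd[pos[c.a]] * sd[pos[c.b]])
        k += 1

    return SEMFit(
        model=model,
        moments=moments,
        labels=labels,
        estimates=theta,
        se=se,
        critical_ratio=cr,
        standardized=std,
        sigma=Sigma,
        f_min=F,
        chi_square=chi2,
        df=df,
        p_value=p_value,
        converged=converged,
        iterations=iterations,
        warnings=warns,
    )


def baseline_model(moments: SampleMoments, chi2_multiplier: str = "n-1") -> SEMFit:
    """Independence (null) model: free variances, all covariances zero.

    Closed form: Σ̂ = diag(S), F = −ln|R| with R the sample correlation
    matrix, χ²_b = (N−1)·F, df_b = p(p−1)/2.
    """
    S, N = moments.S, moments.n
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise FitError("sample correlation matrix is not positive definite")
    F = float(-logdet)
    mult = (N - 1) if chi2_multiplier == "n-1" else N
    chi2 = mult * F
    df = p * (p - 1) // 2
    model = PathModel(variables=list(moments.variables), paths=[], covariances=[],
                      name="independence")
    theta = np.diag(S).copy()
    se = np.sqrt(2.0 / mult) * np.diag(S)
    return SEMFit(
        model=model,
        moments=moments,
        labels=model.parameter_labels,
        estimates=theta,
        se=se,
        critical_ratio=theta / se,
        standardized=np.full(p, np.nan),
        sigma=np.diag(np.diag(S)),
        f_min=F,
        chi_square=chi2,
        df=df,
        p_value=chi_square_p(chi2, df) if df >= 1 else float("nan"),
        converged=True,
        iterations=0,
    )
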