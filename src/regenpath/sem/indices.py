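"""Descriptive goodness-of-fit indices for a fitted path model.

Absolute residual indices (RMR, SRMR), the GFI/AGFI pair, the incremental
indices referenced to the independence baseline (NFI, RFI, IFI, CFI), their
parsimony-weighted versions (PNFI, PCFI) and RMSEA.  The closed-form pieces
are exposed as standalone helpers so an index can be recomputed from printed
χ²/df/GFI values alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import SEMFit


@dataclass
class FitIndices:
    rmr: float
    srmr: float
    gfi: float
    agfi: float
    nfi: float
    rfi: float
    ifi: float
    cfi: float
    pnfi: float
    pcfi: float
    rmsea: float
    notes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("rmr", "srmr", "gfi", "agfi", "nfi", "rfi", "ifi", "cfi",
                 "pnfi", "pcfi", "rmsea")}


def agfi_from_gfi(gfi: float, p: int, df: int) -> float:
    """AGFI = 1 − [p(p+1)/(2·df)]·(1 − GFI): GFI adjusted for model df."""
    if df <= 0:
        return float("nan")
    return float(1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi))


def incremental_indices(chi_m: float, df_m: int, chi_b: float, df_b: int) -> dict:
    """NFI/RFI/IFI/CFI and their parsimony versions from the two χ² fits."""
    nfi = float((chi_b - chi_m) / chi_b) if chi_b > 0 else float("nan")
    if df_m > 0 and chi_b > 0:
        rfi = float(1.0 - (chi_m / df_m) / (chi_b / df_b))
    else:
        rfi = float("nan")
    ifi = float((chi_b - chi_m) / (chi_b - df_m)) if chi_b != df_m else float("nan")
    denom = max(chi_m - df_m, chi_b - df_b, 0.0)
    cfi = float(1.0 - max(chi_m - df_m, 0.0) / denom) if denom > 0 else 1.0
    pnfi = float((df_m / df_b) * nfi) if df_b > 0 else float("nan")
    pcfi = float((df_m / df_b) * cfi) if df_b > 0 else float("nan")
    return {"nfi": nfi, "rfi": rfi, "ifi": ifi, "cfi": cfi, "pnfi": pnfi, "pcfi": pcfi}


def baseline_chi_square_from_nfi(chi_m: float, nfi: float) -> float:
    """Invert NFI = (χ²_b − χ²_m)/χ²_b for the baseline χ²."""
    if not 0 < nfi < 1:
        raise ValueError("NFI must lie strictly between 0 and 1")
    return float(chi_m / (1.0 - nfi))


def rmsea(chi_m: float, df_m: int, n: int) -> float:
    """RMSEA = √(max(χ² − df, 0) / (df·(N−1)))."""
    if df_m <= 0:
        return float("nan")
    return float(np.sqrt(max(chi_m - df_m, 0.0) / (df_m * (n - 1))))


def gfi_from_matrices(S: np.ndarray, Sigma: np.ndarray) -> float:
    """GFI = 1 − tr[(Σ̂⁻¹S − I)²] / tr[(Σ̂⁻¹S)²]."""
    p = S.shape[0]
    M = np.linalg.inv(Sigma) @ S
    I = np.eye(p)
    return float(1.0 - np.trace((M - I) @ (M - I)) / np.trace(M @ M))


def fit_indices(S: np.ndarray, fit: SEMFit, baseline: SEMFit) -> FitIndices:
    """Compute the full index summary from a model fit and its baseline.

    RMR/SRMR average the (raw / correlation-scale) covariance residuals over
    the p(p+1)/2 distinct moments; with df_m = 0 the AGFI and RMSEA are
    undefined and reported as NaN with a note.
    """
    if not (fit.converged and baseline.converged):
        raise ValueError("fit indices require converged model and baseline fits")
    S = np.asarray(S, dtype=float)
    Sigma = fit.sigma
    p = S.shape[0]
    n_moments = p * (p + 1) // 2
    iu = np.triu_indices(p)
    resid = (S - Sigma)[iu]
    rmr_val = float(np.sqrt(np.sum(resid**2) / n_moments))
    scale = np.sqrt(np.outer(np.diag(S), np.diag(S)))[iu]
    srmr = float(np.sqrt(np.sum((resid / scale) ** 2) / n_moments))

    gfi = gfi_from_matrices(S, Sigma)
    notes: list[str] = []
    if fit.df <= 0:
        notes.append("AGFI undefined: model has zero degrees of freedom")
        notes.append("RMSEA undefined: model has zero degrees of freedom")
    inc = incremental_indices(fit.chi_square, fit.df, baseline.chi_square, baseline.df)
    return FitIndices(
        rmr=rmr_val,
        srmr=srmr,
        gfi=gfi,
        agfi=agfi_from_gfi(gfi, p, fit.df),
        rmsea=rmsea(fit.chi_square, fit.df, fit.n),
        notes=tuple(notes),
        **inc,
    )
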