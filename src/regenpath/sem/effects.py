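"""Direct, indirect and total effect decomposition for acyclic path models.

With A the p×p matrix of fitted path coefficients (A[dst, src]), the total
effect matrix is (I−A)⁻¹ − I; the indirect effect is total minus direct.
The standardized decomposition applies the same algebra to the standardized
coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import SEMFit
from .model import PathModel


def _coef_matrix(model: PathModel, values: np.ndarray) -> np.ndarray:
    pos = {v: i for i, v in enumerate(model.variables)}
    A = np.zeros((model.p, model.p))
    for k, e in enumerate(model.paths):
        A[pos[e.dst], pos[e.src]] = values[k]
    return A


def effects_from_coefficients(
    model: PathModel,
    b: np.ndarray,
    beta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Effect decomposition from path-coefficient values in path order.

    ``b`` (and optionally ``beta`` for the standardized scale) hold one value
    per directed path, in ``model.paths`` order.  Lets published coefficient
    tables be decomposed without refitting.
    """
    I = np.eye(model.p)
    scales = {"b": np.asarray(b, dtype=float)}
    if beta is not None:
        scales["beta"] = np.asarray(beta, dtype=float)
    out = {}
    for scale, values in scales.items():
        A = _coef_matrix(model, values)
        total = np.linalg.inv(I - A) - I
        out[scale] = {"direct": A, "indirect": total - A, "total": total}
    pos = {v: i for i, v in enumerate(model.variables)}
    rows = []
    for dst in model.endogenous:
        for src in model.variables:
            if src == dst:
                continue
            i, j = pos[dst], pos[src]
            row = {"source": src, "target": dst}
            for scale in scales:
                for kind in ("direct", "indirect", "total"):
                    row[f"{kind}_{scale}"] = out[scale][kind][i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def effects_decomposition(fit: SEMFit, model: PathModel | None = None) -> pd.DataFrame:
    """Per (source, target) pair: direct/indirect/total effects, b and β scale.

    Only pairs with an endogenous target are reported.  For an acyclic model
    the matrix series (I−A)⁻¹ − I = A + A² + … terminates, so the indirect
    effect equals the sum over all directed routes of length ≥ 2 of the
    products of their edge coefficients.
    """
    model = model or fit.model
    if not fit.converged:
        raise ValueError("effects require a converged fit")
    n_paths = len(model.paths)
    return effects_from_coefficients(
        model, fit.estimates[:n_paths], fit.standardized[:n_paths]
    )


def effect(effects: pd.DataFrame, source: str, target: str) -> pd.Series:
    """Select the decomposition row for one source → target pair."""
    row = effects[(effects["source"] == source) & (effects["target"] == target)]
    if row.empty:
        raise KeyError(f"no effect row for {source} -> {target}")
    return row.iloc[0]
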