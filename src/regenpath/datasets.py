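"""Packaged fixtures: the triticale path model and its published moments.

The anther-culture study this package models reported only summary tables —
per-variable means/variances, the Pearson correlation matrix (n = 37), the
path diagram and its fitted coefficients.  Those summaries ship here as JSON
and are reconstructed into usable objects: a :class:`PathModel`, a
:class:`SampleMoments` covariance (S = D^{1/2} R D^{1/2}) and a parameter
vector of the reported estimates, which doubles as the default generating
truth for simulations.

The reconstruction carries the published tables' own internal rounding
inconsistencies (e.g. the correlation-implied covariance differs from the
reported ML covariance estimates), so it is suitable for demonstrations and
simulation truths, not for exact re-derivation of the reported fit.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .sem.fit import SampleMoments
from .sem.model import PathModel, build_model
from .simulate import SimulationTruth


def _load_json(name: str) -> dict:
    ref = resources.files("regenpath.data") / name
    return json.loads(ref.read_text())


def triticale_path_model() -> PathModel:
    """The five-variable triticale model: Cu/Ag/CHH_DNMV exogenous (three free
    covariances), CHH_SV and GPRE endogenous with six directed paths."""
    return build_model(_load_json("triticale_path_model.json"))


def triticale_summary() -> dict:
    """Raw published summary record (means, variances, correlations, estimates)."""
    return _load_json("triticale_moments.json")


def triticale_moments() -> SampleMoments:
    """Covariance matrix reconstructed from published variances and correlations."""
    from .pipeline import reconstruct_covariance

    summ = triticale_summary()
    variables = summ["variables"]
    variances = {v: summ["variances"][v] for v in variables}
    R = np.asarray(summ["correlations"], dtype=float)
    return reconstruct_covariance(variances, R, n=summ["n"], variables=variables)


def triticale_truth() -> SimulationTruth:
    """Reported path-model estimates as a simulation truth vector.

    Parameter order follows ``triticale_path_model().parameter_labels``;
    means are the published per-variable means, and the metAFLP event rates
    default to the published CHH means (SV 8.65%, DNMV 0.58%, DMV 0.76%).
    """
    summ = triticale_summary()
    model = triticale_path_model()
    est = summ["reported_estimates"]
    theta = np.array([est[lab] for lab in model.parameter_labels])
    return SimulationTruth(theta=theta, means=dict(summ["means"]))


def triticale_reported_ses() -> np.ndarray:
    """Published standard errors in parameter-label order (for comparisons)."""
    summ = triticale_summary()
    model = triticale_path_model()
    return np.array([summ["reported_standard_errors"][lab] for lab in model.parameter_labels])
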