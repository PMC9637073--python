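"""End-to-end orchestration: regeneration statistics, covariance
reconstruction from summary tables, and the staged analysis run.

The full pipeline runs score → describe → correlate → regress → lasso → sem
→ effects → indices on synthetic or user-supplied inputs and writes TSV/JSON
report files, each stamped with the seed and a config hash so reruns are
mechanically comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .datasets import triticale_path_model, triticale_truth
from .scoring import (
    EventClassificationTable,
    default_classification_table,
    profiles_to_wide,
    quantify_variation,
)
from .sem.effects import effects_decomposition
from .sem.fit import FitOptions, SampleMoments, baseline_model, fit_ml
from .sem.indices import fit_indices
from .sem.model import PathModel
from .simulate import DesignSpec, SimulationTruth, simulate_design, simulate_metaflp


@dataclass
class RegenerationRecord:
    """Per-treatment anther-culture outcome counts."""

    treatment: str
    anthers_plated: int
    green_regenerants: int
    albino_regenerants: int

    def __post_init__(self) -> None:
        for name in ("anthers_plated", "green_regenerants", "albino_regenerants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gpre(record: RegenerationRecord) -> float:
    """Green plant regeneration efficiency: green regenerants per 100 plated anthers."""
    if record.anthers_plated <= 0:
        raise ValueError("anthers_plated must be positive")
    return 100.0 * record.green_regenerants / record.anthers_plated


def albino_fraction(records: list[RegenerationRecord]) -> float:
    """Percent of all regenerants (green + albino) that are albinotic."""
    green = sum(r.green_regenerants for r in records)
    albino = sum(r.albino_regenerants for r in records)
    if green + albino == 0:
        raise ValueError("no regenerants in the supplied records")
    return 100.0 * albino / (green + albino)


def reconstruct_covariance(
    variances: dict[str, float] | np.ndarray,
    correlations: np.ndarray,
    n: int,
    variables: list[str] | None = None,
) -> SampleMoments:
    """Rebuild a covariance matrix from variances and correlations.

    S = D^{1/2} R D^{1/2}.  Raises if |r| > 1 or any variance is non-positive;
    the SampleMoments constructor then verifies positive definiteness.
    """
    if isinstance(variances, dict):
        if variables is None:
            variables = list(variances)
        var = np.array([variances[v] for v in variables], dtype=float)
    else:
        var = np.asarray(variances, dtype=float)
        if variables is None:
            variables = [f"v{i}" for i in range(len(var))]
    R = np.asarray(correlations, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(R) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    d = np.sqrt(var)
    S = R * np.outer(d, d)
    return SampleMoments(S=S, n=n, variables=list(variables))


STAGES = ("score", "describe", "correlate", "regress", "lasso", "sem", "effects", "indices")


@dataclass
class RunConfig:
    out_dir: str | Path = "regenpath_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    design: DesignSpec | None = None
    truth: SimulationTruth | None = None
    model: PathModel | None = None
    classification_table: EventClassificationTable | None = None
    n_markers_per_context: dict[str, int] | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "stages": self.stages,
                "design": None if self.design is None else self.design.treatments,
                "theta": None
                if (self.truth is None or self.truth.theta is None)
                else list(map(float, self.truth.theta)),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"seed": config.seed, "config_hash": config.config_hash(), **payload}
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the enabled stages on a synthetic experiment bundle.

    Generates the treatment design and marker matrices with the configured
    truth, scores them, runs the statistical stages, and fits the path model
    on the simulated per-regenerant table.  Returns a manifest dict (also
    written to ``manifest.json``) listing each completed stage and its output
    files.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"stages": [], "files": [], "warnings": []}

    model = config.model or triticale_path_model()
    truth = config.truth or triticale_truth()
    if config.n_markers_per_context is not None:
        truth = dataclasses.replace(
            truth, markers_per_context=dict(config.n_markers_per_context)
        )
    table = config.classification_table or default_classification_table()
    design = simulate_design(config.design or DesignSpec(seed=config.seed))
    n_reg = len(design)

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# seed={config.seed} config={config.config_hash()}\n")
            df.to_csv(fh, sep="\t", index=False)
        manifest["files"].append(str(path))

    # synthetic inputs shared by several stages
    mat_a, mat_k = simulate_metaflp(truth, n_reg, seed=int(rng.integers(2**31)))
    profiles = quantify_variation(mat_a, mat_k, table)
    wide = profiles_to_wide(profiles).reindex([f"R{j}" for j in range(1, n_reg + 1)])
    data = design.copy()
    for col in ("CHH_SV", "CHH_DNMV", "CHH_DMV"):
        data[col] = wide[col].to_numpy()
    # outcome drawn from the path model given the design covariates
    sem_noise = _draw_outcomes(model, truth, data, seed=int(rng.integers(2**31)))
    data["GPRE"] = sem_noise

    if "score" in config.stages:
        emit("variation_profiles.tsv", profiles)
        manifest["stages"].append("score")

    analysis_vars = ["Ag_uM", "Cu_uM", "CHH_DNMV", "CHH_SV", "GPRE"]
    renamed = data[analysis_vars].rename(columns={"Ag_uM": "Ag", "Cu_uM": "Cu"})

    if "describe" in config.stages:
        emit("descriptives.tsv", st.describe_table(renamed).reset_index(names="variable"))
        manifest["stages"].append("describe")

    if "correlate" in config.stages:
        corr = st.pearson_matrix(renamed)
        emit("correlations.tsv", corr.r.reset_index(names="variable"))
        emit("correlation_pvalues.tsv", corr.p.reset_index(names="variable"))
        manifest["stages"].append("correlate")

    if "regress" in config.stages:
        fit = st.ols_fit(renamed["GPRE"], renamed[["Cu"]])
        _stamp(out / "regression.json", {"fit": fit.__dict__}, config)
        manifest["files"].append(str(out / "regression.json"))
        manifest["stages"].append("regress")

    if "lasso" in config.stages:
        X = data[["Cu_uM", "Ag_uM", "time_days", "CHH_SV", "CHH_DNMV", "CHH_DMV"]]
        lfit = st.lasso_fit(data["GPRE"], X, k_folds=min(10, len(data)), seed=config.seed)
        _stamp(
            out / "lasso.json",
            {
                "optimal_lambda": lfit.optimal_lambda,
                "intercept": lfit.intercept,
                "slopes": lfit.slopes,
            },
            config,
        )
        manifest["files"].append(str(out / "lasso.json"))
        manifest["stages"].append("lasso")

    sem_fit = base = None
    if {"sem", "effects", "indices"} & set(config.stages):
        moments = SampleMoments.from_data(renamed[model.variables])
        sem_fit = fit_ml(model, moments, FitOptions(seed=config.seed))
        base = baseline_model(moments)
        manifest["warnings"].extend(sem_fit.warnings)

    if "sem" in config.stages:
        emit("path_estimates.tsv", sem_fit.summary().reset_index(names="parameter"))
        _stamp(
            out / "sem_fit.json",
            {
                "chi_square": sem_fit.chi_square,
                "df": sem_fit.df,
                "p_value": sem_fit.p_value,
                "converged": sem_fit.converged,
                "iterations": sem_fit.iterations,
            },
            config,
        )
        manifest["files"].append(str(out / "sem_fit.json"))
        manifest["stages"].append("sem")

    if "effects" in config.stages:
        emit("effects.tsv", effects_decomposition(sem_fit))
        manifest["stages"].append("effects")

    if "indices" in config.stages:
        idx = fit_indices(sem_fit.moments.S, sem_fit, base)
        _stamp(out / "fit_indices.json", idx.as_dict(), config)
        manifest["files"].append(str(out / "fit_indices.json"))
        manifest["stages"].append("indices")

    _stamp(out / "manifest.json", manifest, config)
    return manifest


def _draw_outcomes(
    model: PathModel, truth: SimulationTruth, data: pd.DataFrame, seed: int
) -> np.ndarray:
    """GPRE given observed covariates via the structural equation + residual."""
    rng = np.random.default_rng(seed)
    labels = model.parameter_labels
    theta = truth.theta
    coef = {lab: theta[i] for i, lab in enumerate(labels)}
    colmap = {"Cu": "Cu_uM", "Ag": "Ag_uM"}
    gpre_val = np.zeros(len(data))
    for e in model.paths:
        if e.dst != "GPRE":
            continue
        src = colmap.get(e.src, e.src)
        gpre_val = gpre_val + coef[e.label] * data[src].to_numpy(dtype=float)
    resid_sd = float(np.sqrt(coef["resid_GPRE"]))
    mean_shift = truth.means.get("GPRE", 0.0)
    centered = gpre_val - gpre_val.mean()
    return mean_shift + centered + rng.normal(0.0, resid_sd, size=len(data))
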