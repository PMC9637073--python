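"""Observed-variable path-model structure.

A recursive (acyclic) path model over p observed variables is parameterised by

* ``B`` — the p×p matrix of path coefficients (B[dst, src] = coefficient of
  the directed edge src → dst; strictly acyclic),
* ``Psi`` — the symmetric p×p covariance matrix of exogenous variables and
  endogenous residuals: free variances/covariances in the exogenous block,
  one residual variance per endogenous variable, residuals mutually
  uncorrelated and uncorrelated with the exogenous variables.

The model-implied covariance is Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx


class ModelError(ValueError):
    """Structurally invalid path model."""


@dataclass(frozen=True)
class Path:
    src: str
    dst: str
    label: str


@dataclass(frozen=True)
class CovarianceEdge:
    a: str
    b: str
    label: str


@dataclass
class PathModel:
    """Validated path-model structure with a fixed free-parameter order.

    Free parameters are ordered: paths (input order), exogenous variances
    (variable order), exogenous covariances (input order), residual variances
    (endogenous variable order).
    """

    variables: list[str]
    paths: list[Path]
    covariances: list[CovarianceEdge] = field(default_factory=list)
    name: str = "path-model"

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ModelError("duplicate variable names")
        known = set(self.variables)
        for e in self.paths:
            if e.src not in known or e.dst not in known:
                raise ModelError(f"path {e.label} references unknown variable")
            if e.src == e.dst:
                raise ModelError(f"self-loop on {e.src}")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.src, e.dst) for e in self.paths)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ModelError(f"directed paths contain a cycle: {cycle}")
        endo = set(self.endogenous)
        for c in self.covariances:
            if c.a not in known or c.b not in known:
                raise ModelError(f"covariance {c.label} references unknown variable")
            if c.a in endo or c.b in endo:
                raise ModelError(
                    f"covariance {c.label} touches an endogenous variable; only "
                    "exogenous variables may covary freely"
                )

    @property
    def endogenous(self) -> list[str]:
        targets = {e.dst for e in self.paths}
        return [v for v in self.variables if v in targets]

    @property
    def exogenous(self) -> list[str]:
        targets = {e.dst for e in self.paths}
        return [v for v in self.variables if v not in targets]

    @property
    def p(self) -> int:
        return len(self.variables)

    def parents(self, var: str) -> list[str]:
        return [e.src for e in self.paths if e.dst == var]

    @property
    def parameter_labels(self) -> list[str]:
        labels = [e.label for e in self.paths]
        labels += [f"var_{v}" for v in self.exogenous]
        labels += [c.label for c in self.covariances]
        labels += [f"resid_{v}" for v in self.endogenous]
        return labels

    @property
    def n_free(self) -> int:
        return len(self.parameter_labels)


def build_model(spec: dict | str | Path) -> PathModel:
    """Build a validated PathModel from a dict or a JSON file.

    The spec lists ``variables``, directed ``paths`` ([{from, to, label}])
    and exogenous ``covariances`` ([{a, b, label}]).
    """
    if not isinstance(spec, dict):
        spec = json.loads(Path(spec).read_text())
    paths = [
        Path(src=e["from"], dst=e["to"], label=e.get("label", f"b_{e['from']}_{e['to']}"))
        for e in spec.get("paths", [])
    ]
    covs = [
        CovarianceEdge(a=c["a"], b=c["b"], label=c.get("label", f"cov_{c['a']}_{c['b']}"))
        for c in spec.get("covariances", [])
    ]
    return PathModel(
        variables=list(spec["variables"]),
        paths=paths,
        covariances=covs,
        name=spec.get("name", "path-model"),
    )


def count_df(model: PathModel) -> int:
    """Degrees of freedom: p(p+1)/2 distinct moments minus free parameters."""
    p = model.p
    df = p * (p + 1) // 2 - model.n_free
    if df < 0:
        raise ModelError(
            f"model is under-identified: {model.n_free} free parameters for "
            f"{p * (p + 1) // 2} distinct sample moments"
        )
    return df
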