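"""Synthetic data generators for the anther-culture experiment.

Three generators cover every input the pipeline needs without any external
download: the 8-treatment induction-medium design, multivariate outcome data
drawn from a path model's implied covariance, and paired metAFLP marker
matrices with planted per-context event rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import MISSING, MarkerMatrix, Platform, default_classification_table
from .sem.fit import implied_covariance
from .sem.model import PathModel

#: Default treatments: Cu(II) uM in {0.1, 5, 10}, Ag(I) uM in {0, 10, 60},
#: induction time in {35, 42, 49} days; group sizes 3-6 totalling 37
#: regenerants, the highest-copper / silver-free condition last.
DEFAULT_TREATMENTS: tuple[tuple[str, float, float, int, int], ...] = (
    ("A", 0.1, 10.0, 35, 4),
    ("B", 0.1, 60.0, 42, 3),
    ("C", 0.1, 0.0, 49, 4),
    ("D", 5.0, 0.0, 35, 5),
    ("E", 5.0, 10.0, 42, 6),
    ("F", 5.0, 60.0, 49, 4),
    ("G", 10.0, 10.0, 42, 5),
    ("H", 10.0, 0.0, 49, 6),
)

CU_LEVELS = (0.1, 5.0, 10.0)
AG_LEVELS = (0.0, 10.0, 60.0)
TIME_LEVELS = (35, 42, 49)


@dataclass
class DesignSpec:
    """Treatment layout: (label, Cu uM, Ag uM, time days, group size)."""

    treatments: tuple[tuple[str, float, float, int, int], ...] = DEFAULT_TREATMENTS
    seed: int = 0
    strict_levels: bool = True

    def __post_init__(self) -> None:
        for label, cu, ag, t, size in self.treatments:
            if size < 1:
                raise ValueError(f"treatment {label}: group size must be >= 1")
            if self.strict_levels and (
                cu not in CU_LEVELS or ag not in AG_LEVELS or t not in TIME_LEVELS
            ):
                raise ValueError(
                    f"treatment {label}: levels ({cu}, {ag}, {t}) outside the "
                    f"design grid Cu{CU_LEVELS} / Ag{AG_LEVELS} / days{TIME_LEVELS}"
                )

    @property
    def total_n(self) -> int:
        return sum(t[-1] for t in self.treatments)


def simulate_design(spec: DesignSpec | None = None) -> pd.DataFrame:
    """One metadata row per regenerant: id, treatment, Cu_uM, Ag_uM, time_days."""
    spec = spec or DesignSpec()
    rows = []
    for label, cu, ag, t, size in spec.treatments:
        for i in range(1, size + 1):
            rows.append(
                {
                    "regenerant_id": f"{label}{i}",
                    "treatment": label,
                    "Cu_uM": cu,
                    "Ag_uM": ag,
                    "time_days": t,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimulationTruth:
    """Generating parameters for the SEM and metAFLP generators.

    ``theta`` is a parameter vector in the order of ``model.parameter_labels``
    (paths, exogenous variances, exogenous covariances, residual variances).
    Event rates are fractions in [0, 1] with r_sv + r_dnmv + r_dmv <= 1.
    """

    theta: np.ndarray | None = None
    means: dict[str, float] = field(default_factory=dict)
    r_sv: float = 0.0865
    r_dnmv: float = 0.0058
    r_dmv: float = 0.0076
    markers_per_context: dict[str, int] = field(
        default_factory=lambda: {"CG": 183, "CHG": 196, "CHH": 218}
    )
    band_freq: float = 0.6  # donor Acc65I band frequency (given KpnI present)
    kpn_absent_freq: float = 0.0  # donor loci invisible to KpnI (enables COMPLEX)
    complex_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.r_sv, self.r_dnmv, self.r_dmv, self.complex_rate)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("event rates must lie in [0, 1]")
        if self.r_sv + self.r_dnmv + self.r_dmv + self.complex_rate > 1:
            raise ValueError("event rates must sum to at most 1")
        if self.complex_rate > 0 and self.kpn_absent_freq <= 0:
            raise ValueError("complex_rate > 0 requires kpn_absent_freq > 0")


def simulate_sem_dataset(
    model: PathModel,
    truth: SimulationTruth,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw n observations from the multivariate normal implied by the model.

    The sample covariance converges to Σ(θ) as n grows, which is what makes
    parameter-recovery checks of the fitting engine possible.
    """
    if truth.theta is None:
        raise ValueError("SimulationTruth.theta is required for SEM simulation")
    sigma = implied_covariance(truth.theta, model)
    if np.any(np.linalg.eigvalsh(sigma) <= 0):
        raise ValueError(
            "implied covariance is not positive definite for the supplied "
            f"parameters (labels: {model.parameter_labels})"
        )
    mu = np.array([truth.means.get(v, 0.0) for v in model.variables])
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(mu, sigma, size=n, method="cholesky")
    return pd.DataFrame(x, columns=model.variables)


def simulate_metaflp(
    truth: SimulationTruth,
    n_regenerants: int,
    seed: int = 0,
) -> tuple[MarkerMatrix, MarkerMatrix]:
    """Paired Acc65I/MseI and KpnI/MseI matrices with planted event rates.

    The donor KpnI band is present unless the locus is drawn KpnI-absent
    (``kpn_absent_freq``); given KpnI presence the donor Acc65I band is
    present with probability ``band_freq``.  Each marker × regenerant pair is
    then independently assigned SV / DNMV / DMV / COMPLEX / no-change.  A
    de novo methylation event is only writable at a donor-unmethylated locus
    (Acc65I present) and a demethylation event only at a donor-methylated one
    (Acc65I absent), so the conditional probabilities are inflated by the
    corresponding locus-class frequency to keep the *marginal* planted rates
    unbiased.  Regenerant patterns are written so that scoring with the
    default classification table recovers exactly the planted events.
    """
    rng = np.random.default_rng(seed)
    contexts = []
    for ctx, m in truth.markers_per_context.items():
        contexts.extend([ctx] * m)
    n_markers = len(contexts)
    if n_markers < 1:
        raise ValueError("need at least one marker")

    p_kpn = 1.0 - truth.kpn_absent_freq
    p_unmeth = p_kpn * truth.band_freq  # donor (Acc=1, Kpn=1)
    p_meth = p_kpn * (1.0 - truth.band_freq)  # donor (Acc=0, Kpn=1)

    cond = {}
    for name, rate, prefix_p in (
        ("dnmv", truth.r_dnmv, p_unmeth),
        ("dmv", truth.r_dmv, p_meth),
        ("complex", truth.complex_rate, truth.kpn_absent_freq),
    ):
        if rate > 0 and prefix_p <= 0:
            raise ValueError(f"{name} rate > 0 but its donor locus class has frequency 0")
        cond[name] = rate / prefix_p if prefix_p > 0 else 0.0
        if truth.r_sv + cond[name] > 1:
            raise ValueError(
                f"conditional {name} probability {cond[name]:.3f} plus SV rate "
                "exceeds 1; lower the rate or adjust the donor band frequencies"
            )

    u = rng.random(n_markers)
    k_donor = (u < p_kpn).astype(np.int8)
    a_donor = np.where((u < p_unmeth) & (k_donor == 1), 1, 0).astype(np.int8)

    a = np.empty((n_markers, n_regenerants + 1), dtype=np.int8)
    k = np.empty_like(a)
    a[:, 0], k[:, 0] = a_donor, k_donor

    for j in range(1, n_regenerants + 1):
        v = rng.random(n_markers)
        a_reg = a_donor.copy()
        k_reg = k_donor.copy()
        sv = v < truth.r_sv
        # SV: flip the KpnI state, keep Acc65I — always an xx10/xx01 code
        k_reg[sv] = 1 - k_reg[sv]
        unmeth = (a_donor == 1) & (k_donor == 1)
        meth = (a_donor == 0) & (k_donor == 1)
        absent = k_donor == 0
        dnmv = unmeth & ~sv & (v < truth.r_sv + cond["dnmv"])
        a_reg[dnmv] = 0  # 1011
        dmv = meth & ~sv & (v < truth.r_sv + cond["dmv"])
        a_reg[dmv] = 1  # 0111
        cpx = absent & ~sv & (v < truth.r_sv + cond["complex"])
        a_reg[cpx] = 1 - a_reg[cpx]  # 0100 or 1000
        a[:, j], k[:, j] = a_reg, k_reg

    individuals = ["donor"] + [f"R{j}" for j in range(1, n_regenerants + 1)]
    marker_ids = [f"m{i:04d}" for i in range(n_markers)]
    mat_a = MarkerMatrix(Platform.ACC65I_MSEI, marker_ids, list(contexts), individuals, a)
    mat_k = MarkerMatrix(Platform.KPNI_MSEI, marker_ids, list(contexts), individuals, k)
    return mat_a, mat_k
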