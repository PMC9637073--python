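"""metAFLP event scoring.

metAFLP profiles each locus twice, with the methylation-sensitive Acc65I and
its methylation-tolerant isoschizomer KpnI (both cut GGTACC).  Comparing the
donor plant's band with a regenerant's band on both platforms yields a 4-digit
binary code (Acc65I donor, Acc65I regenerant, KpnI donor, KpnI regenerant).
Each of the 16 possible codes is classified as one of:

* ``NO_CHANGE`` — identical restriction behaviour in donor and regenerant,
* ``SV``        — sequence variation (the methylation-insensitive KpnI pattern
                  changed, so the recognition site itself changed),
* ``DNMV``      — de novo methylation (KpnI constant-present, Acc65I band lost
                  in the regenerant),
* ``DMV``       — demethylation (KpnI constant-present, Acc65I band gained),
* ``COMPLEX``   — patterns not attributable to a single event.

Percentages of each category per sequence context (CG/CHG/CHH) quantify
tissue-culture-induced variation per regenerant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # internal code for an unscorable cell

CONTEXTS = ("CG", "CHG", "CHH")
CATEGORIES = ("NO_CHANGE", "SV", "DNMV", "DMV", "COMPLEX")


class Platform(str, Enum):
    ACC65I_MSEI = "ACC65I_MSEI"
    KPNI_MSEI = "KPNI_MSEI"


class MarkerMatrixError(ValueError):
    """Malformed or inconsistent marker-matrix input."""


@dataclass
class MarkerMatrix:
    """Binary band presence/absence matrix for one enzyme platform.

    Rows are markers, columns are individuals; the first individual is the
    donor plant, the rest are regenerants.  ``values`` holds 0/1 with
    ``MISSING`` (-1) for unscorable cells.
    """

    platform: Platform
    marker_ids: list[str]
    context: list[str]
    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n_markers, n_ind = self.values.shape
        if n_markers < 1 or n_ind < 2:
            raise MarkerMatrixError(
                "need at least 1 marker and 2 individuals (donor + regenerant), "
                f"got shape {self.values.shape}"
            )
        if len(self.marker_ids) != n_markers or len(self.context) != n_markers:
            raise MarkerMatrixError("marker_ids/context length does not match values")
        if len(self.individuals) != n_ind:
            raise MarkerMatrixError("individuals length does not match values")
        if len(set(self.marker_ids)) != n_markers:
            dupes = sorted({m for m in self.marker_ids if self.marker_ids.count(m) > 1})
            raise MarkerMatrixError(f"duplicate marker ids: {dupes}")
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MarkerMatrixError(
                f"value out of {{0,1,missing}} at marker {self.marker_ids[i]!r}, "
                f"individual {self.individuals[j]!r}"
            )
        unknown = sorted(set(self.context) - set(CONTEXTS))
        if unknown:
            raise MarkerMatrixError(f"unknown sequence contexts: {unknown}")

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def donor(self) -> str:
        return self.individuals[0]

    @property
    def regenerants(self) -> list[str]:
        return self.individuals[1:]


def read_marker_matrix(
    path: str | Path,
    platform: Platform | str,
    context_column: str = "context",
    id_column: str = "marker_id",
    missing_token: str = "NA",
    sep: str | None = None,
) -> MarkerMatrix:
    """Read a marker × individual 0/1 matrix from CSV/TSV.

    Expected layout: one row per marker with columns ``id_column``,
    ``context_column`` and then one column per individual, donor first.
    Cells must be 0, 1 or ``missing_token``; anything else raises
    :class:`MarkerMatrixError` naming the offending row and column.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (id_column, context_column):
        if col not in df.columns:
            raise MarkerMatrixError(f"missing required column {col!r} in {path}")
    individuals = [c for c in df.columns if c not in (id_column, context_column)]
    values = np.empty((len(df), len(individuals)), dtype=np.int8)
    for j, col in enumerate(individuals):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == missing_token:
                values[i, j] = MISSING
            elif cell in ("0", "1"):
                values[i, j] = int(cell)
            else:
                raise MarkerMatrixError(
                    f"cannot parse cell {cell!r} at row {df[id_column].iloc[i]!r}, "
                    f"column {col!r} (expected 0, 1 or {missing_token!r})"
                )
    return MarkerMatrix(
        platform=Platform(platform),
        marker_ids=df[id_column].tolist(),
        context=df[context_column].tolist(),
        individuals=individuals,
        values=values,
    )


def write_marker_matrix(matrix: MarkerMatrix, path: str | Path, missing_token: str = "NA") -> None:
    """Write a MarkerMatrix in the CSV dialect `read_marker_matrix` expects."""
    cells = matrix.values.astype(object)
    cells[matrix.values == MISSING] = missing_token
    df = pd.DataFrame(cells, columns=matrix.individuals)
    df.insert(0, "context", matrix.context)
    df.insert(0, "marker_id", matrix.marker_ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Event codes and classification


@dataclass(frozen=True)
class EventClassificationTable:
    """Total mapping from each of the 16 four-digit codes to an event category."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = {f"{i:04b}" for i in range(16)}
        if set(self.mapping) != codes:
            missing = sorted(codes - set(self.mapping))
            extra = sorted(set(self.mapping) - codes)
            raise ValueError(
                f"classification table must map all 16 codes exactly once; "
                f"missing={missing}, unexpected={extra}"
            )
        bad = sorted(set(self.mapping.values()) - set(CATEGORIES))
        if bad:
            raise ValueError(f"unknown event categories: {bad}")
        for code in ("0000", "1111"):
            if self.mapping[code] != "NO_CHANGE":
                raise ValueError(f"code {code} must map to NO_CHANGE")

    def __getitem__(self, code: str) -> str:
        return self.mapping[code]


def read_classification_table(path: str | Path) -> EventClassificationTable:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return EventClassificationTable({r["code"]: r["category"] for r in rows})


def default_classification_table() -> EventClassificationTable:
    """The shipped default table (versioned CSV inside the package).

    KpnI donor≠regenerant → SV; KpnI constant-present with Acc65I loss → DNMV,
    with Acc65I gain → DMV; platform-constant codes → NO_CHANGE; the two
    KpnI-absent single-platform changes → COMPLEX.
    """
    ref = resources.files("regenpath.data") / "event_classification.csv"
    with resources.as_file(ref) as p:
        return read_classification_table(p)


def derive_code(a_donor: int, a_reg: int, k_donor: int, k_reg: int) -> str:
    """Concatenate the four band states into the 4-digit event code.

    Order: Acc65I donor, Acc65I regenerant, KpnI donor, KpnI regenerant.
    Any missing state makes the code unscorable (returns ``""``).
    """
    states = (a_donor, a_reg, k_donor, k_reg)
    if any(s == MISSING for s in states):
        return ""
    if any(s not in (0, 1) for s in states):
        raise ValueError(f"band states must be 0/1/missing, got {states}")
    return "".join(str(s) for s in states)


def classify_code(code: str, table: EventClassificationTable) -> str:
    """Look up the event category of a 4-digit code."""
    try:
        return table[code]
    except KeyError:
        raise ValueError(f"code {code!r} not covered by the classification table") from None


# ---------------------------------------------------------------------------
# Quantification


def _check_aligned(matrix_a: MarkerMatrix, matrix_k: MarkerMatrix) -> None:
    if matrix_a.marker_ids != matrix_k.marker_ids:
        mism = [
            (x, y) for x, y in zip(matrix_a.marker_ids, matrix_k.marker_ids) if x != y
        ][:10]
        raise MarkerMatrixError(f"marker ids differ between platforms, e.g. {mism}")
    if matrix_a.individuals != matrix_k.individuals:
        raise MarkerMatrixError(
            "individual order differs between platforms: "
            f"{matrix_a.individuals} vs {matrix_k.individuals}"
        )
    if matrix_a.context != matrix_k.context:
        raise MarkerMatrixError("context labels differ between platforms")


def quantify_variation(
    matrix_a: MarkerMatrix,
    matrix_k: MarkerMatrix,
    table: EventClassificationTable | None = None,
) -> pd.DataFrame:
    """Score every (marker, regenerant) code and return tidy variation profiles.

    For each regenerant and each sequence context (plus ``ALL``), the
    percentage of each event category is 100 × count / denominator, where the
    denominator is the number of scorable codes in that context (codes with a
    missing band state on either platform are excluded from numerator and
    denominator alike).

    Returns a DataFrame with columns regenerant_id, context, category, count,
    denominator, percentage.
    """
    if table is None:
        table = default_classification_table()
    _check_aligned(matrix_a, matrix_k)

    context = np.asarray(matrix_a.context)
    rows: list[dict] = []
    a = matrix_a.values
    k = matrix_k.values
    a_donor, k_donor = a[:, 0], k[:, 0]
    lut = np.array([table[f"{i:04b}"] for i in range(16)])
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    lut_idx = np.array([cat_index[c] for c in lut])

    for j, reg in enumerate(matrix_a.regenerants, start=1):
        a_reg, k_reg = a[:, j], k[:, j]
        scorable = (
            (a_donor != MISSING) & (a_reg != MISSING)
            & (k_donor != MISSING) & (k_reg != MISSING)
        )
        code_num = (a_donor * 8 + a_reg * 4 + k_donor * 2 + k_reg).astype(int)
        cats = np.where(scorable, lut_idx[np.clip(code_num, 0, 15)], -1)
        for ctx in (*CONTEXTS, "ALL"):
            in_ctx = np.ones_like(scorable) if ctx == "ALL" else (context == ctx)
            denom = int((scorable & in_ctx).sum())
            for cat in CATEGORIES:
                count = int(((cats == cat_index[cat]) & in_ctx).sum())
                rows.append(
                    {
                        "regenerant_id": reg,
                        "context": ctx,
                        "category": cat,
                        "count": count,
                        "denominator": denom,
                        "percentage": 100.0 * count / denom if denom else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def profiles_to_wide(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy profiles to one row per regenerant with CTX_CAT columns.

    Column names follow the field convention, e.g. ``CHH_SV``, ``CG_DNMV``;
    the ``ALL`` context keeps its prefix (``ALL_SV``).
    """
    sub = profiles[profiles["category"].isin(("SV", "DNMV", "DMV"))].copy()
    sub["variable"] = sub["context"] + "_" + sub["category"]
    wide = sub.pivot(index="regenerant_id", columns="variable", values="percentage")
    wide.columns.name = None
    return wide


def polymorphism_rate(matrix: MarkerMatrix) -> float:
    """Percent of markers whose non-missing band states vary across individuals.

    A marker enters the denominator only if it has at least two non-missing
    values; it is polymorphic if those values are not all equal.
    """
    vals = matrix.values
    poly = 0
    informative = 0
    for row in vals:
        obs = row[row != MISSING]
        if obs.size >= 2:
            informative += 1
            if not np.all(obs == obs[0]):
                poly += 1
    if informative == 0:
        raise MarkerMatrixError("no marker has two or more non-missing values")
    return 100.0 * poly / informative


def context_from_primer(primer: str) -> str:
    """Map a selective-primer name to its sequence context.

    Primer names carry the 3'-end selective bases: ``-CG``/``-CHG`` prefixes
    mark the symmetric contexts; any combination of A and T marks the
    asymmetric CHH context.
    """
    name = primer.upper()
    if name.startswith("CG"):
        return "CG"
    if name.startswith("CHG"):
        return "CHG"
    suffix = name.split("-")[-1]
    if suffix and set(suffix) <= {"A", "T"}:
        return "CHH"
    raise ValueError(f"cannot infer sequence context from primer {primer!r}")
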