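"""metAFLP event coding, classification and variation quantification."""

import numpy as np
import pandas as pd
import pytest

from regenpath.scoring import (
    MISSING,
    EventClassificationTable,
    MarkerMatrix,
    MarkerMatrixError,
    Platform,
    classify_code,
    context_from_primer,
    default_classification_table,
    derive_code,
    polymorphism_rate,
    profiles_to_wide,
    quantify_variation,
    read_marker_matrix,
    write_marker_matrix,
)
from regenpath.simulate import SimulationTruth, simulate_metaflp


def make_pair(codes, context="CHH"):
    """Build aligned platform matrices (donor + 1 regenerant) from 4-digit codes."""
    a = np.array([[int(c[0]), int(c[1])] for c in codes], dtype=np.int8)
    k = np.array([[int(c[2]), int(c[3])] for c in codes], dtype=np.int8)
    ids = [f"m{i}" for i in range(len(codes))]
    ctx = [context] * len(codes)
    ind = ["donor", "R1"]
    return (
        MarkerMatrix(Platform.ACC65I_MSEI, ids, ctx, ind, a),
        MarkerMatrix(Platform.KPNI_MSEI, ids, ctx, ind, k),
    )


@pytest.mark.parametrize(
    "states, code",
    [((1, 1, 1, 1), "1111"), ((0, 0, 0, 0), "0000"), ((1, 0, 1, 1), "1011")],
)
def test_derive_code_concatenates_in_platform_order(states, code):
    assert derive_code(*states) == code


def test_derive_code_missing_state_is_unscorable():
    assert derive_code(1, MISSING, 1, 1) == ""


@pytest.mark.parametrize(
    "code, category",
    [
        ("1111", "NO_CHANGE"),
        ("0000", "NO_CHANGE"),
        ("0011", "NO_CHANGE"),
        ("1100", "NO_CHANGE"),
        ("1010", "SV"),
        ("0001", "SV"),
        ("1011", "DNMV"),
        ("0111", "DMV"),
        ("0100", "COMPLEX"),
        ("1000", "COMPLEX"),
    ],
)
def test_default_table_classification(code, category, table):
    assert classify_code(code, table) == category


def test_default_table_is_total(table):
    cats = [table[f"{i:04b}"] for i in range(16)]
    assert len(cats) == 16
    assert cats.count("SV") == 8  # every KpnI donor/regenerant difference


def test_partial_or_inconsistent_tables_rejected(table):
    mapping = dict(table.mapping)
    mapping.pop("0101")
    with pytest.raises(ValueError, match="all 16 codes"):
        EventClassificationTable(mapping)
    mapping = dict(table.mapping)
    mapping["1111"] = "SV"
    with pytest.raises(ValueError, match="NO_CHANGE"):
        EventClassificationTable(mapping)


def test_single_sv_among_twenty_chh_markers_gives_five_percent(table):
    codes = ["1010"] + ["1111"] * 19
    a, k = make_pair(codes)
    prof = quantify_variation(a, k, table)
    wide = profiles_to_wide(prof)
    assert wide.loc["R1", "CHH_SV"] == pytest.approx(5.0)
    assert wide.loc["R1", "CHH_DNMV"] == 0.0
    assert wide.loc["R1", "CHH_DMV"] == 0.0


def test_regenerant_identical_to_donor_scores_zero_everywhere(table):
    codes = ["1111"] * 7 + ["0000"] * 5 + ["0011"] * 3
    a, k = make_pair(codes)
    prof = quantify_variation(a, k, table)
    changed = prof[prof["category"].isin(("SV", "DNMV", "DMV", "COMPLEX"))]
    assert (changed["percentage"].dropna() == 0).all()


def test_counts_sum_to_scorable_denominator(table):
    rngl = np.random.default_rng(5)
    truth = SimulationTruth(r_sv=0.1, r_dnmv=0.02, r_dmv=0.02,
                            markers_per_context={"CG": 30, "CHG": 30, "CHH": 40})
    a, k = simulate_metaflp(truth, 4, seed=11)
    # punch some holes to exercise the unscorable path
    a.values[rngl.integers(0, 100, 25), rngl.integers(0, 5, 25)] = MISSING
    prof = quantify_variation(a, k, table)
    for (_, ctx), grp in prof.groupby(["regenerant_id", "context"]):
        assert grp["count"].sum() == grp["denominator"].iloc[0]


def test_marker_order_permutation_leaves_profiles_unchanged(table):
    truth = SimulationTruth(r_sv=0.1, r_dnmv=0.02, r_dmv=0.02,
                            markers_per_context={"CG": 25, "CHH": 40})
    a, k = simulate_metaflp(truth, 3, seed=2)
    perm = np.random.default_rng(0).permutation(a.n_markers)

    def shuffled(m):
        return MarkerMatrix(
            m.platform,
            [m.marker_ids[i] for i in perm],
            [m.context[i] for i in perm],
            m.individuals,
            m.values[perm],
        )

    before = quantify_variation(a, k, table)
    after = quantify_variation(shuffled(a), shuffled(k), table)
    key = ["regenerant_id", "context", "category"]
    pd.testing.assert_frame_equal(
        before.sort_values(key).reset_index(drop=True),
        after.sort_values(key).reset_index(drop=True),
    )


def test_misaligned_matrices_rejected(table):
    a, k = make_pair(["1111", "1010"])
    k2 = MarkerMatrix(k.platform, ["x0", "x1"], k.context, k.individuals, k.values)
    with pytest.raises(MarkerMatrixError, match="marker ids differ"):
        quantify_variation(a, k2, table)


class TestPolymorphismRate:
    def test_constant_matrix(self):
        a, _ = make_pair(["1111"] * 6)
        assert polymorphism_rate(a) == 0.0

    def test_every_marker_varies(self):
        a, _ = make_pair(["1011"] * 4)  # Acc65I donor 1, regenerant 0
        assert polymorphism_rate(a) == 100.0

    def test_four_of_ten(self):
        codes = ["1011"] * 4 + ["1111"] * 6
        a, _ = make_pair(codes)
        assert polymorphism_rate(a) == pytest.approx(40.0)

    def test_markers_without_two_observations_excluded(self):
        vals = np.array([[1, MISSING], [1, 0], [0, 0]], dtype=np.int8)
        m = MarkerMatrix(Platform.ACC65I_MSEI, ["a", "b", "c"], ["CG"] * 3,
                         ["donor", "R1"], vals)
        assert m.values[0, 1] == MISSING
        assert polymorphism_rate(m) == pytest.approx(50.0)


class TestMarkerMatrixIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "marker_id,context,donor,R1,R2\n"
            "m1,CHH,1,0,NA\n"
            "m2,CG,0,1,1\n"
        )
        m = read_marker_matrix(path, Platform.ACC65I_MSEI)
        assert (m.n_markers, len(m.individuals)) == (2, 3)
        assert m.values[0, 2] == MISSING
        out = tmp_path / "out.csv"
        write_marker_matrix(m, out)
        again = read_marker_matrix(out, Platform.ACC65I_MSEI)
        assert np.array_equal(m.values, again.values)
        assert again.individuals == ["donor", "R1", "R2"]

    def test_bad_cell_value_names_row_and_column(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("marker_id,context,donor,R1\nm1,CHH,1,2\n")
        with pytest.raises(MarkerMatrixError, match="'2'.*'m1'.*'R1'"):
            read_marker_matrix(path, Platform.ACC65I_MSEI)

    def test_duplicate_marker_id_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("marker_id,context,donor,R1\nm1,CHH,1,1\nm1,CG,0,0\n")
        with pytest.raises(MarkerMatrixError, match="duplicate"):
            read_marker_matrix(path, Platform.ACC65I_MSEI)

    def test_full_size_simulated_matrix_reports_597_markers(self, tmp_path, truth):
        a, _ = simulate_metaflp(truth, 3, seed=0)
        path = tmp_path / "full.csv"
        write_marker_matrix(a, path)
        m = read_marker_matrix(path, Platform.ACC65I_MSEI)
        assert m.n_markers == 597


@pytest.mark.parametrize(
    "primer, ctx",
    [("CG-GAC", "CG"), ("CHG-AGA", "CHG"), ("CHH-ATT", "CHH"), ("X-TAA", "CHH")],
)
def test_context_from_primer_suffix(primer, ctx):
    assert context_from_primer(primer) == ctx
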