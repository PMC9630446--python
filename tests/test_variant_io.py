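import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vusannot as v
from vusannot.variant_io import FormatError, ValidationError


def test_read_toy_tsv(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text("protein_id\tposition\twt_aa\tmut_aa\n"
                 "MLL1\t4000\tA\tV\nMLL1\t4001\tG\tD\nMLL2\t5300\tK\tE\n")
    table = v.read_variant_table(p)
    assert len(table) == 3
    assert [mv.position for mv in table.variants] == [4000, 4001, 5300]


def test_synonymous_row_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("protein_id\tposition\twt_aa\tmut_aa\nMLL1\t4000\tA\tA\n")
    with pytest.raises(ValidationError, match="row 0"):
        v.read_variant_table(p)


@pytest.mark.parametrize("header", ["protein_id\tposition\twt_aa",
                                    "id\tpos\twt\tmut"])
def test_missing_mandatory_header(tmp_path, header):
    p = tmp_path / "bad.tsv"
    p.write_text(header + "\nMLL1\t1\tA\n")
    with pytest.raises(FormatError):
        v.read_variant_table(p)


def test_unparseable_position_named(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("protein_id\tposition\twt_aa\tmut_aa\nMLL1\tNA\tA\tV\n")
    with pytest.raises(FormatError, match="rows \\[0\\]"):
        v.read_variant_table(p)


def test_duplicate_variant_rejected():
    df = pd.DataFrame({"protein_id": ["A", "A"], "position": [5, 5],
                       "wt_aa": ["G", "G"], "mut_aa": ["A", "A"]})
    with pytest.raises(ValidationError, match="duplicate"):
        v.VariantTable(df)


def test_write_read_round_trip(default_bundle, tmp_path):
    p = tmp_path / "variants.tsv"
    v.write_variant_table(default_bundle.table, p)
    again = v.read_variant_table(p)
    pd.testing.assert_frame_equal(
        again.df, default_bundle.table.df[again.df.columns], check_dtype=False)
    # byte stability: writing the re-read table reproduces the file exactly
    p2 = tmp_path / "again.tsv"
    v.write_variant_table(again, p2)
    assert p.read_bytes() == p2.read_bytes()


def test_alignment_width_and_members(ungapped_pair_alignment):
    assert ungapped_pair_alignment.width == 10
    assert len(ungapped_pair_alignment.members) == 3


def test_ragged_fasta_rejected(tmp_path):
    p = tmp_path / "ragged.fa"
    p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIK\n")
    with pytest.raises(FormatError):
        v.read_alignment(p, "fasta")


def test_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">a\nACDEF\n>a\nACDEF\n")
    with pytest.raises(FormatError, match="duplicate"):
        v.read_alignment(p, "fasta")


def test_clustal_fasta_equivalence(tmp_path):
    fasta = tmp_path / "aln.fa"
    fasta.write_text(">s1\nAC-DEF\n>s2\nACXDEF\n".replace("X", "G"))
    clustal = tmp_path / "aln.aln"
    clustal.write_text(
        "CLUSTAL W (1.82) multiple sequence alignment\n\n"
        "s1              AC-DEF\n"
        "s2              ACGDEF\n")
    a1 = v.read_alignment(fasta, "fasta")
    a2 = v.read_alignment(clustal, "clustal")
    assert a1.sequences == a2.sequences


def test_dot_gap_normalized():
    aln = v.ParalogAlignment({"a": "AC.DE", "b": "ACGDE"})
    assert aln.sequences["a"] == "AC-DE"


def test_coordinate_map_identity(ungapped_pair_alignment):
    cmap = v.build_coordinate_map(ungapped_pair_alignment, "A",
                                  {"A": 1, "B": 1, "C": 1})
    for i in range(1, 11):
        assert cmap.column_from_local("A", i) == i
        assert cmap.local_from_column("B", i) == i


def test_coordinate_map_hand_traced_insertion():
    # B equals A with A's 2-residue head removed; A's head columns are gaps in B
    aln = v.ParalogAlignment({"A": "GSACDEF", "B": "--ACDEF"})
    cmap = v.build_coordinate_map(aln, "A", {"A": 1, "B": 1})
    assert cmap.column_from_local("B", 1) == 3
    assert cmap.column_from_local("A", 1) == 1
    assert cmap.local_from_column("B", 1) is None
    assert cmap.local_from_column("A", 3) == 3


def test_reference_numbering_offset():
    aln = v.ParalogAlignment({"A": "ACDEF", "B": "ACDEF"})
    cmap = v.build_coordinate_map(aln, "A", {"A": 3745, "B": 100})
    assert cmap.column_from_full("A", 3745) == 1
    assert cmap.full_from_column("A", 5) == 3749
    assert cmap.reference_label(5) == "3749"


def test_reference_label_falls_back_at_gap():
    aln = v.ParalogAlignment({"A": "AC--F", "B": "ACDEF"})
    cmap = v.build_coordinate_map(aln, "A", {"A": 10, "B": 1})
    assert cmap.reference_label(3) == "11+"


def test_coordinate_map_errors(ungapped_pair_alignment):
    with pytest.raises(ValidationError):
        v.build_coordinate_map(ungapped_pair_alignment, "missing",
                               {"A": 1, "B": 1, "C": 1})
    with pytest.raises(ValidationError):
        v.build_coordinate_map(ungapped_pair_alignment, "A",
                               {"A": 0, "B": 1, "C": 1})


@st.composite
def gapped_alignment(draw):
    n_cols = draw(st.integers(5, 30))
    n_seqs = draw(st.integers(2, 5))
    seqs = {}
    for i in range(n_seqs):
        chars = draw(st.lists(
            st.sampled_from(list("ACDEFG-")), min_size=n_cols, max_size=n_cols))
        if all(c == "-" for c in chars):
            chars[0] = "A"
        seqs[f"s{i}"] = "".join(chars)
    return v.ParalogAlignment(seqs)


@settings(max_examples=50, deadline=None)
@given(gapped_alignment())
def test_round_trip_and_monotone_on_random_gapped(aln):
    """local -> column -> local is the identity; columns strictly increase."""
    offsets = {pid: 1 for pid in aln.members}
    cmap = v.build_coordinate_map(aln, aln.members[0], offsets)
    for pid in aln.members:
        cols = [cmap.column_from_local(pid, i)
                for i in range(1, cmap.n_residues(pid) + 1)]
        assert cols == sorted(set(cols))  # strictly increasing
        for i, c in enumerate(cols, start=1):
            assert cmap.local_from_column(pid, c) == i


def test_validate_variants_flags():
    aln = v.ParalogAlignment({"A": "ACDEF", "B": "ACDEF"})
    offsets = {"A": 10, "B": 1}
    df = pd.DataFrame({
        "protein_id": ["A", "A", "A"],
        "position": [10, 11, 99],            # A10=A ok; A11 is C, not G; 99 out
        "wt_aa": ["A", "G", "A"],
        "mut_aa": ["V", "D", "V"],
    })
    report = v.validate_variants(v.VariantTable(df), aln, offsets)
    assert list(report["flag"]) == ["ok", "wt_mismatch", "out_of_range"]


def test_synthetic_bundle_consistent_with_its_alignment(default_bundle):
    """Every generated variant's wild-type residue matches its sequence."""
    report = v.validate_variants(default_bundle.table, default_bundle.alignment,
                                 default_bundle.offsets)
    assert (report["flag"] == "ok").all()
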