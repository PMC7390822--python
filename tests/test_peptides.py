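"""Variant parsing, application, windowing and peptide-pair enumeration."""

import pytest
from hypothesis import given, settings, strategies as st

from neoclone.peptides import (
    DEFAULT_K_RANGE,
    MutantWindow,
    ProteinRecord,
    ProteinVariant,
    ReferenceMismatchError,
    UnsupportedVariantError,
    VariantKind,
    VariantParseError,
    apply_protein_variant,
    enumerate_peptide_pairs,
    extract_window,
    pad_context,
    parse_variant_label,
    peptide_pairs_for_variant,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_mutant_kmers(wt: str, mutant: str, ks=DEFAULT_K_RANGE) -> set[str]:
    """Independent oracle: every k-mer of the mutant protein absent from the
    wild-type protein."""
    out = set()
    for k in ks:
        for i in range(len(mutant) - k + 1):
            kmer = mutant[i : i + k]
            if kmer not in wt:
                out.add(kmer)
    return out


# --- parsing ---------------------------------------------------------------


@pytest.mark.parametrize(
    "label,kind,start,end,ref,alt",
    [
        ("A161T", VariantKind.SUBSTITUTION, 161, 161, "A", "T"),
        ("E746_A750del", VariantKind.INFRAME_DELETION, 746, 750, "EA", ""),
        ("K745del", VariantKind.INFRAME_DELETION, 745, 745, "K", ""),
        ("K745_E746insT", VariantKind.INFRAME_INSERTION, 745, 745, "KE", "T"),
    ],
)
def test_parse_variant_label(label, kind, start, end, ref, alt):
    v = parse_variant_label(label)
    assert (v.kind, v.start, v.end, v.ref_aa, v.alt_aa) == (kind, start, end, ref, alt)
    assert v.label == label  # round-trips


@pytest.mark.parametrize(
    "label,err",
    [
        ("A1A", VariantParseError),  # null variant
        ("not-a-variant", VariantParseError),
        ("A161", VariantParseError),
        ("E746_A745del", VariantParseError),  # end before start
        ("K745_E747insT", VariantParseError),  # non-adjacent insertion anchors
        ("E746fs", UnsupportedVariantError),
        ("R342*", UnsupportedVariantError),
    ],
)
def test_parse_variant_label_rejects(label, err):
    with pytest.raises(err):
        parse_variant_label(label)


# --- application -----------------------------------------------------------


def test_apply_deletion_joins_flanks(table1_contexts):
    rec = table1_contexts["EGFR"]
    mut = apply_protein_variant(rec, parse_variant_label("E746_A750del"))
    assert mut == "IPVAIKTSPKANK"


def test_apply_substitution(table1_contexts):
    rec = table1_contexts["TP53"]
    mut = apply_protein_variant(rec, parse_variant_label("A161T"))
    assert mut == "GTRVRAMTIYKQ"


def test_apply_insertion():
    rec = ProteinRecord("p", "ACDEFGHIK")
    mut = apply_protein_variant(rec, parse_variant_label("D3_E4insWW"))
    assert mut == "ACDWWEFGHIK"


def test_apply_full_length_deletion_yields_empty():
    rec = ProteinRecord("p", "ACDEF")
    v = ProteinVariant(VariantKind.INFRAME_DELETION, 1, 5, "AF", "")
    assert apply_protein_variant(rec, v) == ""
    assert peptide_pairs_for_variant(rec, v) == []


def test_apply_reference_mismatch_reports_position():
    rec = ProteinRecord("p", "ACDEF")
    with pytest.raises(ReferenceMismatchError, match="position 2"):
        apply_protein_variant(rec, parse_variant_label("W2K"))


# --- windowing -------------------------------------------------------------


def test_substitution_window_is_centered_21mer(table1_contexts):
    rec = pad_context(table1_contexts["TP53"], n=20)
    w = extract_window(rec, parse_variant_label("A161T"))
    assert len(w.mutant_context) == 21
    assert w.site_offsets == (10,)
    assert w.mutant_context[10] == "T"
    assert w.wt_context[10] == "A"


def test_substitution_window_truncates_at_terminus():
    rec = ProteinRecord("p", "MKWVTFISLLFLFSSAYSRG")
    v = parse_variant_label("W3G")
    w = extract_window(rec, v)
    # 2 upstream + site + 10 downstream
    assert len(w.mutant_context) == 13
    assert w.site_offsets == (2,)


def test_deletion_window_spans_junction(table1_contexts):
    rec = table1_contexts["EGFR"]
    w = extract_window(rec, parse_variant_label("E746_A750del"))
    assert w.mutant_context == "IPVAIKTSPKANK"
    assert w.junction == 6  # between ...IPVAIK and TSPKANK...
    assert w.covers(5, 9) and not w.covers(6, 7)


# --- enumeration -----------------------------------------------------------


def test_egfr_19del_pairs_match_published_junction_peptides(table1_contexts):
    pairs = peptide_pairs_for_variant(
        table1_contexts["EGFR"], parse_variant_label("E746_A750del")
    )
    ten = {p.mutant_seq: p.wt_seq for p in pairs if p.k == 10}
    assert ten["IPVAIKTSPK"] == "IPVAIKELRE"
    assert ten["AIKTSPKANK"] == "AIKELREATS"


def test_dennd6b_substitution_9mers_match_published(table1_contexts):
    pairs = peptide_pairs_for_variant(
        table1_contexts["DENND6B"], parse_variant_label("R398Q")
    )
    nine = {p.mutant_seq: p.wt_seq for p in pairs if p.k == 9}
    assert nine["QLLKGVQKK"] == "RLLKGVQKK"
    assert nine["KALLKQLLK"] == "KALLKRLLK"
    assert nine["KQLLKGVQK"] == "KRLLKGVQK"


def test_centered_substitution_count_law():
    # repeat-free protein: every k-mer unique, so no self-peptide drops
    seq = "ACDEFGHIKLMNPQRSTVWY" + "YWVTSRQPNMLKIHGFEDCA"[1:]
    rec = ProteinRecord("p", seq[:41])
    v = parse_variant_label(f"{rec.sequence[20]}21{'W' if rec.sequence[20] != 'W' else 'Y'}")
    pairs = peptide_pairs_for_variant(rec, v)
    by_k = {k: sum(1 for p in pairs if p.k == k) for k in (9, 10, 11)}
    assert by_k == {9: 9, 10: 10, 11: 11}
    assert len(pairs) == 30


def test_window_shorter_than_k_yields_empty():
    rec = ProteinRecord("p", "ACDEFGHK")  # length 8 < 9
    assert peptide_pairs_for_variant(rec, parse_variant_label("D3W")) == []


def test_pairs_are_deterministically_ordered_and_unique(table1_contexts):
    rec = table1_contexts["EGFR"]
    v = parse_variant_label("E746_A750del")
    a = peptide_pairs_for_variant(rec, v)
    b = peptide_pairs_for_variant(rec, v)
    assert a == b
    assert [p.k for p in a] == sorted(p.k for p in a)
    assert len({(p.mutant_seq, p.k) for p in a}) == len(a)


# --- oracle equivalence and invariants -------------------------------------

protein_st = st.text(alphabet=AA, min_size=12, max_size=60)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(seq=protein_st, data=st.data())
def test_substitution_matches_brute_force_oracle(seq, data):
    pos = data.draw(st.integers(1, len(seq)))
    alt = data.draw(st.sampled_from([a for a in AA if a != seq[pos - 1]]))
    rec = ProteinRecord("p", seq)
    v = ProteinVariant(VariantKind.SUBSTITUTION, pos, pos, seq[pos - 1], alt)
    mutant = apply_protein_variant(rec, v)
    emitted = {p.mutant_seq for p in peptide_pairs_for_variant(rec, v)}
    assert emitted == brute_force_mutant_kmers(seq, mutant)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(seq=protein_st, data=st.data())
def test_deletion_matches_brute_force_oracle(seq, data):
    start = data.draw(st.integers(1, len(seq) - 1))
    end = data.draw(st.integers(start, min(len(seq), start + 6)))
    rec = ProteinRecord("p", seq)
    v = ProteinVariant(
        VariantKind.INFRAME_DELETION, start, end, seq[start - 1 : end], ""
    )
    mutant = apply_protein_variant(rec, v)
    emitted = {p.mutant_seq for p in peptide_pairs_for_variant(rec, v)}
    assert emitted == brute_force_mutant_kmers(seq, mutant)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=protein_st, data=st.data())
def test_pairs_differ_and_swapped_variant_restores_wild_type(seq, data):
    pos = data.draw(st.integers(1, len(seq)))
    alt = data.draw(st.sampled_from([a for a in AA if a != seq[pos - 1]]))
    rec = ProteinRecord("p", seq)
    v = ProteinVariant(VariantKind.SUBSTITUTION, pos, pos, seq[pos - 1], alt)
    mutant = apply_protein_variant(rec, v)
    # ref/alt swap applied to the mutant recovers the wild type
    back = ProteinVariant(VariantKind.SUBSTITUTION, pos, pos, alt, seq[pos - 1])
    assert apply_protein_variant(ProteinRecord("m", mutant), back) == seq
    for p in peptide_pairs_for_variant(rec, v):
        assert p.mutant_seq != p.wt_seq
        assert sum(a != b for a, b in zip(p.mutant_seq, p.wt_seq)) >= 1


def test_deletion_insertion_duality():
    seq = "MKWVTFISLLFLFSSAYSRG"
    rec = ProteinRecord("p", seq)
    v = parse_variant_label("V4_F6del")
    mutant = apply_protein_variant(rec, v)
    # inserting the deleted residues back after the preceding anchor restores wt
    ins = ProteinVariant(VariantKind.INFRAME_INSERTION, 3, 3, "WI", "VTF")
    assert apply_protein_variant(ProteinRecord("m", mutant), ins) == seq


def test_table1_reconstruction_all_pairs(
    table1_contexts, table1_variants, table1_affinities
):
    """All 13 published mutant peptides regenerate with exact wild-type partners."""
    generated = {}
    for gene, v in table1_variants.items():
        for p in peptide_pairs_for_variant(table1_contexts[gene], v):
            generated[(gene, p.mutant_seq)] = p.wt_seq
    for row in table1_affinities.itertuples():
        assert generated.get((row.gene, row.mutant_peptide)) == row.wt_peptide
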