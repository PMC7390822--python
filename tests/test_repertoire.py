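"""Clonotype tables, Fisher exact expansion test, clone tracking, V-J usage."""

import math

import numpy as np
import pandas as pd
import pytest

from neoclone.repertoire import (
    Clonotype,
    RepertoireSample,
    SignificanceResult,
    detect_significant_clones,
    fisher_one_sided,
    high_frequency_clones,
    load_clonotype_table,
    track_clones,
    vj_usage,
    write_clonotype_table,
)


def brute_force_fisher_upper_p(a: int, total_a: int, b: int, total_b: int) -> float:
    """Independent oracle: exact integer enumeration of the hypergeometric
    upper tail P(X >= a) over all 2x2 tables with the observed margins."""
    n, K, N = total_a, a + b, total_a + total_b
    num = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
    )
    return num / math.comb(N, n)


def make_sample(counts, label="s", v="TRBV9", j="TRBJ2-1"):
    clones = [
        Clonotype(cdr3aa=f"CASS{i}F", v_gene=v, j_gene=j, count=c)
        for i, c in enumerate(counts)
    ]
    return RepertoireSample(label, clones).normalized()


# --- loading ---------------------------------------------------------------


def test_load_clonotype_table_renormalizes(tmp_path):
    p = tmp_path / "clones.tsv"
    p.write_text(
        "count\tfreq\tcdr3nt\tcdr3aa\tv\td\tj\n"
        "50\t0.5\tTGTGCC\tCASSF\tTRBV9\t\tTRBJ2-1\n"
        "30\t0.3\tTGTGCT\tCASTF\tTRBV7\t\tTRBJ1-1\n"
        "20\t0.2\tTGTGCG\tCASRF\tTRBV9\t\tTRBJ1-2\n"
    )
    s = load_clonotype_table(p)
    assert [c.freq for c in s.clonotypes] == [0.5, 0.3, 0.2]
    assert s.total_reads == 100


def test_load_clonotype_table_warns_on_freq_mismatch(tmp_path):
    p = tmp_path / "clones.tsv"
    p.write_text(
        "count\tfreq\tcdr3nt\tcdr3aa\tv\tj\n"
        "50\t0.9\tTGTGCC\tCASSF\tTRBV9\tTRBJ2-1\n"
        "50\t0.1\tTGTGCT\tCASTF\tTRBV7\tTRBJ1-1\n"
    )
    with pytest.warns(UserWarning, match="counts"):
        s = load_clonotype_table(p)
    assert [c.freq for c in s.clonotypes] == [0.5, 0.5]  # counts win


def test_load_clonotype_table_empty_and_missing_column(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("count\tfreq\tcdr3nt\tcdr3aa\tv\tj\n")
    s = load_clonotype_table(empty)
    assert s.clonotypes == [] and s.total_reads == 0
    bad = tmp_path / "bad.tsv"
    bad.write_text("count\tcdr3aa\n1\tCASSF\n")
    with pytest.raises(ValueError, match="missing required columns"):
        load_clonotype_table(bad)


def test_load_clonotype_table_mixcr_aliases(tmp_path):
    p = tmp_path / "mixcr.tsv"
    p.write_text(
        "cloneCount\tcloneFraction\tnSeqCDR3\taaSeqCDR3\tallVHitsWithScore\tallJHitsWithScore\n"
        "10\t1.0\tTGTGCC\tCASSF\tTRBV9*00(1234.5)\tTRBJ2-1*00(99)\n"
    )
    s = load_clonotype_table(p)
    assert s.clonotypes[0].v_gene == "TRBV9"
    assert s.clonotypes[0].j_gene == "TRBJ2-1"


def test_clonotype_roundtrip(tmp_path):
    s = make_sample([5, 3, 2])
    write_clonotype_table(s, tmp_path / "out.tsv")
    back = load_clonotype_table(tmp_path / "out.tsv")
    assert [c.count for c in back.clonotypes] == [5, 3, 2]
    assert sum(c.freq for c in back.clonotypes) == pytest.approx(1.0)


# --- high-frequency definition ---------------------------------------------


def test_high_frequency_cutoff_is_inclusive():
    clones = [
        Clonotype("CASSF", "TRBV9", "TRBJ2-1", 1, freq=f)
        for f in (0.001, 0.00099, 0.5)
    ]
    s = RepertoireSample("s", clones)
    kept = {c.freq for c in high_frequency_clones(s)}
    assert kept == {0.001, 0.5}


def test_uniform_repertoire_all_high_frequency():
    s = make_sample([1] * 1000)
    assert len(high_frequency_clones(s)) == 1000


# --- Fisher test -----------------------------------------------------------


def test_fisher_symmetry_null():
    orr, p = fisher_one_sided(5, 100, 5, 100)
    assert orr == pytest.approx(1.0)
    assert p >= 0.5


def test_fisher_a_zero_gives_p_one():
    _, p = fisher_one_sided(0, 100, 3, 100)
    assert p == pytest.approx(1.0)


def test_fisher_matches_brute_force_on_deep_table():
    a, A, b, B = 20, 1000, 1, 1000
    orr, p = fisher_one_sided(a, A, b, B)
    assert p == pytest.approx(brute_force_fisher_upper_p(a, A, b, B), rel=1e-10)
    assert orr == pytest.approx((a * (B - b)) / ((A - a) * b), rel=1e-12)


def test_fisher_haldane_correction_only_with_zero_cell():
    orr, _ = fisher_one_sided(10, 100, 0, 100)
    assert orr == pytest.approx((10.5 * 100.5) / (90.5 * 0.5))


def test_fisher_exhaustive_small_margins():
    """Implementation equals exact enumeration for all tables, margins <= 12."""
    for A in range(1, 13):
        for B in range(1, 13):
            for a in range(A + 1):
                for b in range(B + 1):
                    _, p = fisher_one_sided(a, A, b, B)
                    assert p == pytest.approx(
                        brute_force_fisher_upper_p(a, A, b, B), rel=1e-9, abs=1e-12
                    ), (a, A, b, B)


def test_fisher_rejects_invalid_margins():
    with pytest.raises(ValueError):
        fisher_one_sided(5, 3, 0, 10)
    with pytest.raises(ValueError):
        fisher_one_sided(0, 0, 0, 0)


# --- significant-clone detection -------------------------------------------


def _stim_pair(mut_counts, wt_counts):
    mut = make_sample(mut_counts, label="mut")
    wt = make_sample(wt_counts, label="wt")
    return mut, wt


def test_expanded_clone_is_significant():
    # clone 0 at 2% in mutant-stimulated vs 0.1% in wt-stimulated, depth 1e5
    depth = 100_000
    mut_counts = [2000] + [98000 // 49] * 49
    wt_counts = [100] + [(depth - 100) // 49] * 49
    mut, wt = _stim_pair(mut_counts, wt_counts)
    results = detect_significant_clones(mut, wt)
    by_key = {r.clone_key: r for r in results}
    r0 = by_key[mut.clonotypes[0].key]
    assert r0.odds_ratio > 10 and r0.p_value < 1e-10 and r0.significant


def test_identical_samples_yield_no_significant_clones():
    mut, wt = _stim_pair([50, 30, 20], [50, 30, 20])
    assert not any(r.significant for r in detect_significant_clones(mut, wt))


def test_singleton_clone_not_significant():
    depth = 100_000
    mut, wt = _stim_pair([1, depth - 1], [0, depth])
    results = detect_significant_clones(mut, wt)
    r = results[0]
    assert r.b == 0 and not r.significant and r.p_value > 0.01


def test_detect_requires_reads():
    mut = RepertoireSample("m", [])
    wt = make_sample([10])
    with pytest.raises(ValueError):
        detect_significant_clones(mut, wt)


def test_bh_correction_is_more_conservative():
    depth = 10_000
    counts_mut = [60] + [100] * 90
    counts_wt = [20] + [100] * 90
    mut, wt = _stim_pair(counts_mut, counts_wt)
    raw = detect_significant_clones(mut, wt, or_cutoff=1.5)
    adj = detect_significant_clones(mut, wt, or_cutoff=1.5, bh_correct=True)
    assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)


# --- tracking --------------------------------------------------------------


def _sig(key):
    return SignificanceResult(key, 10, 100, 0, 100, 20.0, 1e-5, True)


def test_track_clones_statuses():
    base = make_sample([500, 0, 10], label="t0")
    post1 = make_sample([400, 50, 0], label="t1")
    post2 = make_sample([450, 60, 5], label="t2")
    keys = [c.key for c in base.clonotypes]
    tracks = track_clones([base, post1, post2], [_sig(k) for k in keys])
    by = {t.clone_key: t.status for t in tracks}
    assert by[keys[0]] == "persistent_high_frequency"  # high at baseline, always seen
    assert by[keys[1]] == "post_treatment_only"  # absent at baseline
    assert by[keys[2]] == "other"  # low-frequency baseline clone that vanishes


def test_track_single_baseline_sample_degrades_gracefully():
    base = make_sample([5000, 1], label="t0")  # second clone below 1e-3
    keys = [c.key for c in base.clonotypes]
    tracks = track_clones([base], [_sig(k) for k in keys])
    assert [t.status for t in tracks] == ["persistent_high_frequency", "other"]


def test_track_requires_baseline():
    with pytest.raises(ValueError):
        track_clones([], [])


# --- V-J usage -------------------------------------------------------------


def test_vj_usage_single_clone():
    s = make_sample([10])
    m = vj_usage(s)
    assert m.shape == (1, 1) and m.iloc[0, 0] == pytest.approx(1.0)


def test_vj_usage_merges_same_pairing():
    clones = [
        Clonotype("CASSF", "TRBV9", "TRBJ2-1", 30),
        Clonotype("CASTF", "TRBV9", "TRBJ2-1", 10),
        Clonotype("CASRF", "TRBV7", "TRBJ1-1", 60),
    ]
    s = RepertoireSample("s", clones).normalized()
    m = vj_usage(s)
    assert m.loc["TRBV9", "TRBJ2-1"] == pytest.approx(0.4)
    assert m.to_numpy().sum() == pytest.approx(1.0)


def test_vj_usage_margins_match_per_segment_usage():
    rng = np.random.default_rng(7)
    vs = [f"TRBV{i}" for i in rng.integers(1, 6, size=40)]
    js = [f"TRBJ{i}" for i in rng.integers(1, 4, size=40)]
    counts = rng.integers(1, 100, size=40)
    clones = [
        Clonotype(f"CAS{i}F", v, j, int(c))
        for i, (v, j, c) in enumerate(zip(vs, js, counts))
    ]
    s = RepertoireSample("s", clones).normalized()
    m = vj_usage(s)
    v_usage = pd.Series(
        {v: sum(c.freq for c in s.clonotypes if c.v_gene == v) for v in set(vs)}
    )
    assert np.allclose(m.sum(axis=1).sort_index(), v_usage.sort_index())
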