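"""TCR-beta repertoire analysis: clonotype tables, clone tracking, expansion tests.

A clonotype is a unique TCR rearrangement (CDR3 + V segment + J segment) with
a read count and frequency within one sequenced sample. The module consumes
VDJtools/MiXCR-style clonotype tables (raw-read V(D)J alignment is upstream
and out of scope) and provides:

* the high-frequency clone definition (frequency >= 1e-3, inclusive);
* the neoantigen-specificity test: for each clone, a 2x2 contingency table of
  its reads versus all other reads in the mutant-peptide-stimulated culture
  against the wild-type-peptide-stimulated culture, scored by a one-sided
  (enrichment) Fisher exact test; a clone is called significant when the odds
  ratio exceeds 10 AND p < 0.01 (both strict), with a Haldane-Anscombe 0.5
  correction applied to the odds ratio only when a cell is zero;
* longitudinal tracking of significant clones through blood samples,
  classifying each as persistent-high-frequency, post-treatment-only or other;
* V-J segment pairing usage matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

HIGH_FREQUENCY_CUTOFF = 1e-3
ODDS_RATIO_CUTOFF = 10.0
P_VALUE_CUTOFF = 0.01

CloneKey = tuple[str, str, str]  # (cdr3 nt if available else aa, v_gene, j_gene)


@dataclass(frozen=True)
class Clonotype:
    cdr3aa: str
    v_gene: str
    j_gene: str
    count: int
    freq: float = 0.0
    cdr3nt: str = ""

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("negative clonotype count")
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError(f"freq {self.freq} outside [0, 1]")

    @property
    def key(self) -> CloneKey:
        """Clone identity: nucleotide CDR3 when present, else amino-acid CDR3,
        always together with the V and J segment calls."""
        return (self.cdr3nt or self.cdr3aa, self.v_gene, self.j_gene)


@dataclass
class RepertoireSample:
    """One sequenced repertoire: a labelled list of clonotypes.

    ``timepoint`` is months from baseline for blood samples; ``condition``
    tags the sample role ("blood", "mutant_stim" or "wt_stim").
    """

    label: str
    clonotypes: list[Clonotype]
    timepoint: float | None = None
    condition: str = "blood"

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def normalized(self) -> "RepertoireSample":
        """Recompute frequencies from counts (frequencies sum to 1)."""
        total = self.total_reads
        clones = [
            replace(c, freq=(c.count / total if total else 0.0))
            for c in self.clonotypes
        ]
        return RepertoireSample(self.label, clones, self.timepoint, self.condition)

    def by_key(self) -> dict[CloneKey, Clonotype]:
        return {c.key: c for c in self.clonotypes}


@dataclass(frozen=True)
class SignificanceResult:
    """Per-clone mutant-vs-wild-type stimulation contingency outcome."""

    clone_key: CloneKey
    a: int  # clone reads, mutant-stimulated
    total_mut: int
    b: int  # clone reads, wt-stimulated
    total_wt: int
    odds_ratio: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class CloneTrack:
    clone_key: CloneKey
    frequencies: tuple[float, ...]  # per blood timepoint, baseline first
    status: str  # persistent_high_frequency | post_treatment_only | other


_COLUMN_ALIASES: dict[str, str] = {
    # VDJtools dialect
    "count": "count", "#count": "count", "freq": "freq", "cdr3nt": "cdr3nt",
    "cdr3aa": "cdr3aa", "v": "v", "d": "d", "j": "j",
    # MiXCR export dialect
    "clonecount": "count", "clonefraction": "freq", "nseqcdr3": "cdr3nt",
    "aaseqcdr3": "cdr3aa", "allvhitswithscore": "v", "alljhitswithscore": "j",
    "bestvhit": "v", "bestjhit": "j",
}


def load_clonotype_table(
    path: str | Path,
    label: str | None = None,
    timepoint: float | None = None,
    condition: str = "blood",
) -> RepertoireSample:
    """Load a VDJtools/MiXCR-like clonotype TSV into a normalized sample.

    Required columns (any dialect alias): count, freq, cdr3nt, cdr3aa, v, j
    (d optional). Frequencies are renormalized from counts; the stored freq
    column is cross-checked within 1e-6 and a warning is issued on mismatch
    (counts win).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [
        _COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns
    ]
    missing = {"count", "freq", "cdr3nt", "cdr3aa", "v", "j"} - set(df.columns)
    if missing:
        raise ValueError(
            f"clonotype table {path}: missing required columns {sorted(missing)}"
        )
    clones = [
        Clonotype(
            cdr3aa=row.cdr3aa,
            v_gene=_strip_hit(row.v),
            j_gene=_strip_hit(row.j),
            count=int(float(row.count)),
            freq=float(row.freq) if row.freq else 0.0,
            cdr3nt=row.cdr3nt,
        )
        for row in df.itertuples(index=False)
    ]
    sample = RepertoireSample(
        label or Path(path).stem, clones, timepoint=timepoint, condition=condition
    ).normalized()
    stored = np.array([float(r) if r else 0.0 for r in df["freq"]])
    if len(stored) and np.abs(
        stored - np.array([c.freq for c in sample.clonotypes])
    ).max() > 1e-6:
        warnings.warn(
            f"{path}: stored freq column disagrees with counts by >1e-6; "
            "frequencies recomputed from counts",
            stacklevel=2,
        )
    return sample


def _strip_hit(v: str) -> str:
    """MiXCR hit columns carry scores like 'TRBV9*00(1234)'; keep the segment."""
    return v.split("*")[0].split("(")[0].strip()


def write_clonotype_table(sample: RepertoireSample, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "count": c.count, "freq": c.freq, "cdr3nt": c.cdr3nt,
                "cdr3aa": c.cdr3aa, "v": c.v_gene, "d": "", "j": c.j_gene,
            }
            for c in sample.clonotypes
        ],
        columns=["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"],
    )
    df.to_csv(path, sep="\t", index=False)


def high_frequency_clones(
    sample: RepertoireSample, cutoff: float = HIGH_FREQUENCY_CUTOFF
) -> list[Clonotype]:
    """Clones at frequency >= cutoff (inclusive; default 1e-3)."""
    return [c for c in sample.clonotypes if c.freq >= cutoff]


def fisher_one_sided(a: int, total_a: int, b: int, total_b: int) -> tuple[float, float]:
    """Odds ratio and one-sided (enrichment) Fisher exact p for the 2x2 table
    [[a, total_a - a], [b, total_b - b]].

    p is the upper-tail hypergeometric probability P(X >= a) conditional on
    the margins. The odds ratio is the cross-product ratio, with 0.5 added to
    all four cells iff any cell is zero (Haldane-Anscombe); the p-value always
    comes from the uncorrected table.
    """
    if not (0 <= a <= total_a and 0 <= b <= total_b) or total_a <= 0 or total_b <= 0:
        raise ValueError(f"invalid contingency margins a={a}/{total_a}, b={b}/{total_b}")
    c, d = total_a - a, total_b - b
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((c + 0.5) * (b + 0.5))
    else:
        orr = (a * d) / (c * b)
    # P(X >= a) for X ~ Hypergeom(N = total_a + total_b, K = a + b, n = total_a)
    p = float(stats.hypergeom.sf(a - 1, total_a + total_b, a + b, total_a))
    return orr, min(1.0, p)


def detect_significant_clones(
    mutant_stim: RepertoireSample,
    wt_stim: RepertoireSample,
    or_cutoff: float = ODDS_RATIO_CUTOFF,
    p_cutoff: float = P_VALUE_CUTOFF,
    bh_correct: bool = False,
) -> list[SignificanceResult]:
    """Test every clone of the mutant-stimulated culture for expansion over
    the wild-type-stimulated culture.

    A clone absent from the wild-type culture contributes b = 0. Significance
    requires odds ratio > ``or_cutoff`` AND p < ``p_cutoff``, both strict; no
    multiple-testing correction is applied unless ``bh_correct`` is set, in
    which case Benjamini-Hochberg-adjusted p-values are used against
    ``p_cutoff``.
    """
    total_mut = mutant_stim.total_reads
    total_wt = wt_stim.total_reads
    if total_mut == 0 or total_wt == 0:
        raise ValueError("both stimulation samples must contain reads")
    wt_by_key = wt_stim.by_key()
    results = []
    for clone in mutant_stim.clonotypes:
        b = wt_by_key.get(clone.key, None)
        b_count = b.count if b is not None else 0
        orr, p = fisher_one_sided(clone.count, total_mut, b_count, total_wt)
        results.append(
            SignificanceResult(
                clone_key=clone.key,
                a=clone.count,
                total_mut=total_mut,
                b=b_count,
                total_wt=total_wt,
                odds_ratio=orr,
                p_value=p,
                significant=False,
            )
        )
    pvals = np.array([r.p_value for r in results])
    if bh_correct and len(pvals):
        pvals = _benjamini_hochberg(pvals)
    return [
        replace(r, significant=(r.odds_ratio > or_cutoff and p < p_cutoff))
        for r, p in zip(results, pvals)
    ]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def track_clones(
    blood_samples: Sequence[RepertoireSample],
    significant: Iterable[SignificanceResult],
    hf_cutoff: float = HIGH_FREQUENCY_CUTOFF,
) -> list[CloneTrack]:
    """Classify each significant clone against ordered blood samples
    (baseline first).

    persistent_high_frequency: frequency >= ``hf_cutoff`` at baseline and
    detected (>= 1 read) at every subsequent timepoint. post_treatment_only:
    zero reads at baseline, detected in at least one post-treatment sample.
    Anything else: other. With a single (baseline-only) blood sample, tracking
    degrades to baseline status alone.
    """
    if not blood_samples:
        raise ValueError("at least one (baseline) blood sample is required")
    maps = [s.by_key() for s in blood_samples]
    tracks = []
    for res in significant:
        key = res.clone_key
        freqs = tuple(
            (m[key].freq if key in m else 0.0) for m in maps
        )
        counts = [(m[key].count if key in m else 0) for m in maps]
        if freqs[0] >= hf_cutoff and all(c >= 1 for c in counts[1:]):
            status = "persistent_high_frequency"
        elif counts[0] == 0 and any(c >= 1 for c in counts[1:]):
            status = "post_treatment_only"
        else:
            status = "other"
        tracks.append(CloneTrack(clone_key=key, frequencies=freqs, status=status))
    return tracks


def vj_usage(sample: RepertoireSample) -> pd.DataFrame:
    """V x J pairing frequency matrix; entries sum to 1 for a normalized sample."""
    if not sample.clonotypes:
        return pd.DataFrame()
    df = pd.DataFrame(
        {
            "v": [c.v_gene for c in sample.clonotypes],
            "j": [c.j_gene for c in sample.clonotypes],
            "freq": [c.freq for c in sample.clonotypes],
        }
    )
    return df.pivot_table(
        index="v", columns="j", values="freq", aggfunc="sum", fill_value=0.0
    )


def write_vj_long(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a V-J matrix in circos-ready long format: v, j, freq."""
    long = matrix.stack().rename("freq").reset_index()
    long = long[long["freq"] > 0]
    long.to_csv(path, sep="\t", index=False)


def write_significance_table(
    results: Iterable[SignificanceResult], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "cdr3": r.clone_key[0], "v": r.clone_key[1], "j": r.clone_key[2],
                "reads_mutant": r.a, "total_mutant": r.total_mut,
                "reads_wt": r.b, "total_wt": r.total_wt,
                "odds_ratio": r.odds_ratio, "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_clone_tracks(tracks: Iterable[CloneTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        row = {"cdr3": t.clone_key[0], "v": t.clone_key[1], "j": t.clone_key[2],
               "status": t.status}
        for i, f in enumerate(t.frequencies):
            row[f"freq_t{i}"] = f
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
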