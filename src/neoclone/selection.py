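"""Candidate neoantigen selection: expression filter, composite score, counting.

After binder filtering, a candidate peptide survives only if its source gene
is expressed at the transcript level (TPM >= 1 by default), and if a composite
score combining binding strength, mutation type, variant allele frequency,
proteasomal C-terminal cleavage, TAP transport efficiency and gene expression
exceeds zero. Peptides from the same mutation count as one neoantigen.

The score is a configurable weighted sum; the published procedure names the
indexes and the "score > 0" selection rule but not the functional form, so the
defaults here are the package's own documented choice, constrained so that a
strong binder with neutral auxiliary terms scores positive. Cleavage and TAP
predictors are pluggable; neutral 0.5 stubs stand in by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binding import ic50_to_score
from .peptides import PeptidePair, VariantKind


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"gene {self.gene}: negative TPM {self.tpm}")


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the composite selection score.

    Defaults: binding dominates (w_binding=2), every auxiliary index carries
    0.5, and the offset of 1 places the zero of the score so that a peptide
    needs either strong binding or support from several auxiliaries to pass.
    """

    w_binding: float = 2.0
    w_mutation_type: float = 0.5
    w_vaf: float = 0.5
    w_cleavage: float = 0.5
    w_tap: float = 0.5
    w_expression: float = 0.5
    offset: float = 1.0


@dataclass
class CandidateNeoantigen:
    """A peptide pair annotated along the filter cascade."""

    pair: PeptidePair
    ic50_mut: float
    ic50_wt: float | None = None
    tpm: float = 0.0
    vaf: float = 0.0
    kind: VariantKind = VariantKind.SUBSTITUTION
    neo_expression: float = 0.0
    clonality: str | None = None  # "clonal" | "subclonal", set by the CCF step
    score: float | None = None
    selected: bool = False

    @property
    def gene(self) -> str:
        return self.pair.gene

    @property
    def variant_label(self) -> str:
        return self.pair.variant_label


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a gene expression TSV with columns gene, tpm."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path}: missing columns {sorted(missing)}")
    return [ExpressionRecord(str(r.gene), float(r.tpm)) for r in df.itertuples()]


def expression_lookup(expression: Iterable[ExpressionRecord]) -> dict[str, float]:
    return {e.gene: e.tpm for e in expression}


def expression_filter(
    candidates: Sequence[CandidateNeoantigen],
    expression: Iterable[ExpressionRecord],
    tpm_min: float = 1.0,
) -> list[CandidateNeoantigen]:
    """Keep candidates whose source gene is expressed at >= ``tpm_min`` TPM.

    Genes absent from the table are treated as unexpressed (TPM 0). The
    candidates' ``tpm`` annotation is filled as a side effect.
    """
    lookup = expression_lookup(expression)
    kept = []
    for c in candidates:
        c.tpm = lookup.get(c.gene, 0.0)
        if c.tpm >= tpm_min:
            kept.append(c)
    return kept


def neoantigen_expression(vaf: float, tpm: float) -> float:
    """Neoantigen expression as VAF x TPM: the simplest combination monotone
    in both the fraction of mutant reads and the transcript abundance."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if tpm < 0:
        raise ValueError(f"negative tpm {tpm}")
    return vaf * tpm


def _expression_term(tpm: float) -> float:
    import math

    return min(1.0, math.log2(tpm + 1.0) / 10.0)


def composite_score(
    candidate: CandidateNeoantigen,
    weights: ScoreWeights = ScoreWeights(),
    cleavage: float = 0.5,
    tap: float = 0.5,
) -> float:
    """Weighted-sum selection score; peptides scoring > 0 are selected.

    score = w_b * (1 - log(IC50)/log(50000)) + w_m * m + w_v * VAF
          + w_c * cleavage + w_t * tap + w_e * min(1, log2(TPM+1)/10) - offset

    with mutation-type code m = 1 for in-frame indels and 0.5 for
    substitutions. Strictly decreasing in IC50, non-decreasing in every other
    argument.
    """
    m = 1.0 if candidate.kind is not VariantKind.SUBSTITUTION else 0.5
    return (
        weights.w_binding * ic50_to_score(candidate.ic50_mut)
        + weights.w_mutation_type * m
        + weights.w_vaf * candidate.vaf
        + weights.w_cleavage * cleavage
        + weights.w_tap * tap
        + weights.w_expression * _expression_term(candidate.tpm)
        - weights.offset
    )


def score_and_select(
    candidates: Sequence[CandidateNeoantigen],
    weights: ScoreWeights = ScoreWeights(),
    cleavage: float = 0.5,
    tap: float = 0.5,
) -> list[CandidateNeoantigen]:
    """Annotate scores and neoantigen expression; return candidates with score > 0."""
    selected = []
    for c in candidates:
        c.neo_expression = neoantigen_expression(c.vaf, c.tpm)
        c.score = composite_score(c, weights, cleavage, tap)
        c.selected = c.score > 0
        if c.selected:
            selected.append(c)
    return selected


def count_neoantigens(selected: Iterable[CandidateNeoantigen]) -> int:
    """Number of distinct (gene, mutation) groups among selected peptides:
    peptides generated from the same mutation count as one neoantigen."""
    return len({(c.gene, c.variant_label) for c in selected})


def write_candidate_table(
    candidates: Iterable[CandidateNeoantigen], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "gene": c.gene,
                "mutation": c.variant_label,
                "mutant_peptide": c.pair.mutant_seq,
                "wt_peptide": c.pair.wt_seq,
                "ic50_mut": c.ic50_mut,
                "ic50_wt": c.ic50_wt,
                "tpm": c.tpm,
                "vaf": c.vaf,
                "neo_expression": c.neo_expression,
                "clonality": c.clonality,
                "score": c.score,
                "selected": c.selected,
            }
            for c in candidates
        ],
        columns=[
            "gene", "mutation", "mutant_peptide", "wt_peptide", "ic50_mut",
            "ic50_wt", "tpm", "vaf", "neo_expression", "clonality", "score",
            "selected",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
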