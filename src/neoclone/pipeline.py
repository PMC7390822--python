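"""End-to-end orchestration of the neoantigen and TCR-response analyses.

The neoantigen arm chains: variant -> mutant/wild-type peptide pairs ->
MHC-I affinity (external predictions or the packaged stub) -> IC50 < 500 nM
binder filter -> transcript expression filter -> composite score and
selection -> per-mutation neoantigen counting, clonality classification and
TMB/TNB. The TCR arm chains: clonotype tables -> per-clone mutant-vs-wild-type
stimulation Fisher tests -> longitudinal tracking against blood samples ->
V-J usage matrices. Both are deterministic given fixed inputs and report a
filter-funnel summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import binding as mb
from . import repertoire as tcr
from .burden import BurdenSummary, estimate_ccf, summarize_burden
from .config import PipelineConfig
from .peptides import PeptidePair, ProteinRecord, ProteinVariant, peptide_pairs_for_variant
from .selection import (
    CandidateNeoantigen,
    count_neoantigens,
    expression_filter,
    score_and_select,
    ExpressionRecord,
)

logger = logging.getLogger("neoclone")


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class FunnelReport:
    """Counts along the filter cascade, at mutation and peptide level."""

    n_nonsynonymous: int
    n_peptide_pairs: int
    n_binder_peptides: int
    n_binder_mutations: int
    n_expressed_genes: int
    n_candidate_peptides: int
    n_neoantigens: int
    n_clonal_peptides: int
    n_subclonal_peptides: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _affinity(
    peptide: str,
    allele: mb.HLAAllele,
    predictions: Mapping[str, float] | None,
    missing: list[str],
) -> float:
    """Affinity from the supplied prediction table, or from the stub when no
    table is given. A peptide absent from a supplied table is treated as a
    non-binder (50000 nM) and recorded in ``missing`` — external predictor
    outputs routinely list only peptides below a reporting cutoff."""
    if predictions is None:
        return mb.predict_stub([peptide], allele)[0].ic50_nm
    if peptide in predictions:
        return predictions[peptide]
    missing.append(peptide)
    return mb.IC50_MAX_NM


def predictions_as_lookup(preds: Iterable[mb.BindingPrediction]) -> dict[str, float]:
    return {p.peptide: p.ic50_nm for p in preds}


def run_neoantigen_pipeline(
    proteins: Sequence[ProteinRecord],
    variants: Sequence[ProteinVariant],
    expression: Sequence[ExpressionRecord],
    config: PipelineConfig | None = None,
    predictions: Mapping[str, float] | None = None,
) -> tuple[list[CandidateNeoantigen], FunnelReport, BurdenSummary]:
    """Run the full variant-to-neoantigen cascade.

    ``predictions`` maps peptide -> IC50 nM (e.g. from a parsed external
    predictor output); when None, the packaged deterministic stub predictor
    supplies affinities. Returns all candidate peptides that survived the
    binder filter (annotated with every downstream decision), the funnel
    report, and the burden summary.
    """
    config = config or PipelineConfig()
    allele = mb.HLAAllele(config.allele)
    by_id = {p.id: p for p in proteins}
    by_gene = {p.gene: p for p in proteins if p.gene}

    # stage: peptides
    candidates: list[CandidateNeoantigen] = []
    missing: list[str] = []
    n_pairs = 0
    for v in variants:
        rec = by_id.get(v.protein_id) or by_gene.get(v.gene)
        if rec is None:
            raise PipelineError(
                "peptides", f"no protein record for variant {v.gene} {v.label}"
            )
        try:
            pairs = peptide_pairs_for_variant(rec, v, config.flank, config.k_range)
        except ValueError as exc:
            raise PipelineError("peptides", str(exc)) from exc
        n_pairs += len(pairs)
        for pair in pairs:
            candidates.append(
                CandidateNeoantigen(
                    pair=pair,
                    ic50_mut=_affinity(pair.mutant_seq, allele, predictions, missing),
                    ic50_wt=_affinity(pair.wt_seq, allele, predictions, missing),
                    vaf=v.vaf or 0.0,
                    kind=v.kind,
                )
            )
    if missing:
        logger.warning(
            "%d peptides had no supplied affinity prediction; treated as "
            "non-binders (%.0f nM)", len(missing), mb.IC50_MAX_NM,
        )

    # stage: binder filter (mutant peptide IC50, strict <)
    binders = [c for c in candidates if c.ic50_mut < config.binder_threshold_nm]
    n_binder_mutations = len({(c.gene, c.variant_label) for c in binders})

    # stage: expression filter
    expressed = expression_filter(binders, expression, config.tpm_min)
    n_expressed_genes = len({c.gene for c in expressed})

    # stage: scoring and selection
    selected = score_and_select(
        expressed, config.score_weights, config.cleavage, config.tap
    )
    n_neo = count_neoantigens(selected)

    # stage: clonality
    for c in selected:
        est = estimate_ccf(
            c.vaf,
            config.purity,
            config.copy_number,
            config.multiplicity,
            config.ccf_clonal_threshold,
        )
        c.clonality = "clonal" if est.clonal else "subclonal"
    n_clonal = sum(1 for c in selected if c.clonality == "clonal")
    n_subclonal = sum(1 for c in selected if c.clonality == "subclonal")

    funnel = FunnelReport(
        n_nonsynonymous=len(variants),
        n_peptide_pairs=n_pairs,
        n_binder_peptides=len(binders),
        n_binder_mutations=n_binder_mutations,
        n_expressed_genes=n_expressed_genes,
        n_candidate_peptides=len(selected),
        n_neoantigens=n_neo,
        n_clonal_peptides=n_clonal,
        n_subclonal_peptides=n_subclonal,
    )
    burden = summarize_burden(len(variants), n_neo, config.exome_mb)
    logger.info(
        "funnel: %d mutations -> %d binder peptides (%d mutations) -> "
        "%d expressed genes -> %d candidate peptides -> %d neoantigens "
        "(%d clonal / %d subclonal peptides); TMB %.2f (%s), TNB %.2f%s",
        funnel.n_nonsynonymous, funnel.n_binder_peptides, funnel.n_binder_mutations,
        funnel.n_expressed_genes, funnel.n_candidate_peptides, funnel.n_neoantigens,
        funnel.n_clonal_peptides, funnel.n_subclonal_peptides,
        burden.tmb, burden.tmb_class, burden.tnb,
        " (high)" if burden.tnb_high else "",
    )
    return binders, funnel, burden


@dataclass
class TCRReport:
    significant: list[tcr.SignificanceResult]
    tracks: list[tcr.CloneTrack]
    vj_matrices: dict[str, pd.DataFrame]
    n_significant: int
    n_persistent: int
    n_post_only: int


def run_tcr_pipeline(
    blood_samples: Sequence[tcr.RepertoireSample],
    mutant_stim: tcr.RepertoireSample,
    wt_stim: tcr.RepertoireSample,
    config: PipelineConfig | None = None,
) -> TCRReport:
    """Detect neoantigen-specific clones and track them through blood samples.

    ``blood_samples`` must be ordered with the baseline first.
    """
    config = config or PipelineConfig()
    if not blood_samples:
        raise PipelineError("tcr", "at least one baseline blood sample required")
    try:
        significant_all = tcr.detect_significant_clones(
            mutant_stim.normalized(),
            wt_stim.normalized(),
            or_cutoff=config.or_cutoff,
            p_cutoff=config.p_cutoff,
            bh_correct=config.bh_correct,
        )
    except ValueError as exc:
        raise PipelineError("tcr-significant", str(exc)) from exc
    significant = [r for r in significant_all if r.significant]
    tracks = tcr.track_clones(
        [s.normalized() for s in blood_samples], significant, config.hf_cutoff
    )
    vj = {s.label: tcr.vj_usage(s.normalized()) for s in blood_samples}
    n_persistent = sum(t.status == "persistent_high_frequency" for t in tracks)
    n_post = sum(t.status == "post_treatment_only" for t in tracks)
    logger.info(
        "tcr: %d significant clones; %d persistent high-frequency, %d post-treatment-only",
        len(significant), n_persistent, n_post,
    )
    return TCRReport(
        significant=significant,
        tracks=tracks,
        vj_matrices=vj,
        n_significant=len(significant),
        n_persistent=n_persistent,
        n_post_only=n_post,
    )
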