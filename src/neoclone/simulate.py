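"""Synthetic patient cohort generator.

Generates every pipeline input with the statistical structure the analysis
assumes — a somatic mutation set with clonal/subclonal cancer-cell-fraction
structure observed through binomial read sampling under a tumor-purity model,
per-gene expression, and TCR repertoires with power-law (Zipf) clone sizes,
longitudinal persistence, and planted stimulation-specific expansions — so
every stage is testable without any sequencing data.

Planted ground truth (true CCFs, responder clone identities) is emitted as
sidecar "truth" tables that the pipeline itself never reads.

Defaults emulate the study conditions: 84 non-silent somatic mutations (half
clonal), tumor purity 0.6 at 200x variant read depth, ~3/4 of mutated genes
not expressed, a 1e5-read repertoire of 1000 clones sampled at baseline and
every 2 months, and 25 planted neoantigen-responsive clones of which 18 are
persistent high-frequency blood clones and 7 appear only after treatment
start, expanded 20-fold by mutant-peptide stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .burden import expected_vaf
from .peptides import ProteinRecord, ProteinVariant, VariantKind
from .repertoire import Clonotype, RepertoireSample, write_clonotype_table
from .selection import ExpressionRecord

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))
_V_CATALOG = [f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 19, 20, 28, 30)]
_J_CATALOG = [f"TRBJ{i}-{j}" for i, j in ((1, 1), (1, 2), (1, 5), (2, 1), (2, 3), (2, 7))]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; same seed => bit-identical cohort."""

    seed: int = 17
    # genomics
    n_clonal_variants: int = 42
    n_subclonal_variants: int = 42
    protein_length: int = 300
    deletion_fraction: float = 0.1  # in-frame deletions (span 3-5) among variants
    purity: float = 0.6
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.5)
    read_depth_variants: int = 200
    expression_lognormal_params: tuple[float, float] = (1.0, 1.5)
    frac_unexpressed: float = 0.75
    # repertoire
    n_clones: int = 1000
    zipf_alpha: float = 1.2
    repertoire_depth: int = 100_000
    n_timepoints: int = 4  # baseline + every-2-months draws
    persistence_prob: float = 0.9
    n_responders_persistent: int = 18
    n_responders_post_only: int = 7
    expansion_factor: float = 20.0
    responder_blood_freq: float = 3e-3  # planted blood frequency of persistent responders
    responder_stim_freq: float = 1e-3  # planted pre-stimulation culture frequency
    freq_jitter_sigma: float = 0.2  # lognormal wobble of persisting clone weights

    @property
    def n_variants(self) -> int:
        return self.n_clonal_variants + self.n_subclonal_variants

    @property
    def n_responders(self) -> int:
        return self.n_responders_persistent + self.n_responders_post_only

    def validate(self) -> None:
        if self.n_responders > self.n_clones:
            raise ValueError("more planted responders than clones")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        lo, hi = self.subclonal_ccf_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("invalid subclonal ccf range")


@dataclass
class GenomicsTruth:
    proteins: list[ProteinRecord]
    variants: list[ProteinVariant]
    expression: list[ExpressionRecord]
    truth: pd.DataFrame  # gene, ccf_true, clonal_true, vaf_observed


@dataclass
class RepertoireTruth:
    blood_samples: list[RepertoireSample]  # baseline first
    mutant_stim: RepertoireSample
    wt_stim: RepertoireSample
    truth: pd.DataFrame  # cdr3nt, v, j, role (persistent | post_only)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genomics: GenomicsTruth
    repertoire: RepertoireTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def simulate_genomics(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomicsTruth:
    """Proteome + somatic variant table + expression table with planted CCFs.

    One variant per synthetic gene/protein (so variant positions cannot
    collide). Clonal variants carry CCF 1; subclonal CCFs are uniform over the
    configured range. The observed VAF is a binomial draw at the configured
    read depth around the purity-adjusted expected VAF of the diploid
    heterozygous model.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    proteins: list[ProteinRecord] = []
    variants: list[ProteinVariant] = []
    rows = []
    ccfs = np.concatenate(
        [
            np.ones(config.n_clonal_variants),
            rng.uniform(*config.subclonal_ccf_range, size=config.n_subclonal_variants),
        ]
    )
    is_deletion = rng.random(config.n_variants) < config.deletion_fraction
    for i in range(config.n_variants):
        gene = f"GENE{i + 1:04d}"
        seq = _random_protein(rng, config.protein_length)
        rec = ProteinRecord(id=f"{gene}_P", sequence=seq, gene=gene)
        p_alt = expected_vaf(ccfs[i], config.purity)
        vaf = rng.binomial(config.read_depth_variants, p_alt) / config.read_depth_variants
        if is_deletion[i]:
            span = int(rng.integers(3, 6))
            start = int(rng.integers(1, config.protein_length - span))
            v = ProteinVariant(
                VariantKind.INFRAME_DELETION,
                start,
                start + span - 1,
                seq[start - 1 : start + span - 1],
                "",
                gene=gene,
                protein_id=rec.id,
                vaf=float(vaf),
            )
        else:
            pos = int(rng.integers(1, config.protein_length + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice(_AA[_AA != ref]))
            v = ProteinVariant(
                VariantKind.SUBSTITUTION, pos, pos, ref, alt,
                gene=gene, protein_id=rec.id, vaf=float(vaf),
            )
        proteins.append(rec)
        variants.append(v)
        rows.append(
            {
                "gene": gene,
                "mutation": v.label,
                "ccf_true": float(ccfs[i]),
                "clonal_true": bool(ccfs[i] >= 0.999),
                "vaf_observed": float(vaf),
            }
        )
    mu, sigma = config.expression_lognormal_params
    tpms = rng.lognormal(mu, sigma, size=config.n_variants)
    silent = rng.random(config.n_variants) < config.frac_unexpressed
    tpms[silent] = 0.0
    expression = [
        ExpressionRecord(p.gene, float(t)) for p, t in zip(proteins, tpms)
    ]
    return GenomicsTruth(
        proteins=proteins,
        variants=variants,
        expression=expression,
        truth=pd.DataFrame(rows),
    )


def _make_clone_catalog(rng: np.random.Generator, n: int) -> list[Clonotype]:
    clones = []
    for _ in range(n):
        length = int(rng.integers(8, 15))
        aa = "C" + "".join(rng.choice(_AA, size=length)) + "F"
        nt = "".join(rng.choice(_NT, size=3 * (length + 2)))
        clones.append(
            Clonotype(
                cdr3aa=aa,
                v_gene=str(rng.choice(_V_CATALOG)),
                j_gene=str(rng.choice(_J_CATALOG)),
                count=0,
                cdr3nt=nt,
            )
        )
    return clones


def _draw_sample(
    rng: np.random.Generator,
    catalog: Sequence[Clonotype],
    weights: np.ndarray,
    depth: int,
    label: str,
    timepoint: float | None,
    condition: str,
) -> RepertoireSample:
    w = weights / weights.sum()
    counts = rng.multinomial(depth, w)
    clones = [
        replace(c, count=int(k), freq=float(k) / depth)
        for c, k in zip(catalog, counts)
        if k > 0
    ]
    return RepertoireSample(label, clones, timepoint=timepoint, condition=condition)


def simulate_repertoires(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> RepertoireTruth:
    """Longitudinal blood repertoires plus a mutant/wild-type stimulation pair.

    Baseline clone weights follow a Zipf law (rank^-alpha). Post-treatment
    draws keep each background clone with the configured persistence
    probability (its vacated mass moving to a replacement clone of new
    identity) and jitter persisting weights lognormally. Planted persistent
    responders sit at high blood frequency at every timepoint; post-only
    responders have exactly zero baseline weight. The stimulation pair is
    drawn from the final PBMC pool with every responder reset to the
    pre-stimulation culture frequency; the mutant culture multiplies responder
    weights by the expansion factor before renormalization, the wild-type
    culture leaves them untouched.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_clones
    catalog = _make_clone_catalog(rng, n)
    weights = 1.0 / np.arange(1, n + 1, dtype=float) ** config.zipf_alpha
    weights /= weights.sum()

    responder_idx = rng.choice(n, size=config.n_responders, replace=False)
    persistent_idx = responder_idx[: config.n_responders_persistent]
    post_only_idx = responder_idx[config.n_responders_persistent :]

    w = weights.copy()
    w[persistent_idx] = config.responder_blood_freq
    w[post_only_idx] = 0.0

    blood = [
        _draw_sample(
            rng, catalog, w, config.repertoire_depth, "blood_t0", 0.0, "blood"
        )
    ]
    replacement_pool = _make_clone_catalog(rng, n)  # identities for clone turnover
    n_replaced = 0
    catalog_t = list(catalog)
    for t in range(1, config.n_timepoints):
        protected = np.zeros(n, dtype=bool)
        protected[responder_idx] = True
        gone = (rng.random(n) > config.persistence_prob) & ~protected & (w > 0)
        for i in np.flatnonzero(gone):
            if n_replaced < len(replacement_pool):
                catalog_t[i] = replacement_pool[n_replaced]  # same mass, new identity
                n_replaced += 1
        jitter = np.exp(rng.normal(0.0, config.freq_jitter_sigma, size=n))
        w = w * jitter
        w[persistent_idx] = config.responder_blood_freq
        w[post_only_idx] = config.responder_blood_freq  # appear after treatment start
        blood.append(
            _draw_sample(
                rng, catalog_t, w, config.repertoire_depth,
                f"blood_t{t}", 2.0 * t, "blood",
            )
        )

    # stimulation cultures from the final PBMC pool
    culture = w.copy()
    culture[responder_idx] = config.responder_stim_freq
    culture /= culture.sum()
    mutant_w = culture.copy()
    mutant_w[responder_idx] *= config.expansion_factor
    wt_stim = _draw_sample(
        rng, catalog_t, culture, config.repertoire_depth, "wt_stim", None, "wt_stim"
    )
    mutant_stim = _draw_sample(
        rng, catalog_t, mutant_w, config.repertoire_depth,
        "mutant_stim", None, "mutant_stim",
    )

    truth = pd.DataFrame(
        [
            {
                "cdr3nt": catalog[i].cdr3nt,
                "cdr3aa": catalog[i].cdr3aa,
                "v": catalog[i].v_gene,
                "j": catalog[i].j_gene,
                "role": "persistent" if i in set(persistent_idx) else "post_only",
            }
            for i in responder_idx
        ]
    )
    return RepertoireTruth(
        blood_samples=blood, mutant_stim=mutant_stim, wt_stim=wt_stim, truth=truth
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort from one seed (genomics and repertoire use derived streams)."""
    return SimulatedCohort(
        config=config,
        genomics=simulate_genomics(config, np.random.default_rng(config.seed)),
        repertoire=simulate_repertoires(config, np.random.default_rng(config.seed + 1)),
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the cohort as the file bundle the pipeline readers consume,
    with planted truth in sidecar ``truth_*.tsv`` files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "proteome.fasta", "w") as fh:
        for p in cohort.genomics.proteins:
            fh.write(f">{p.id} gene={p.gene} start={p.start}\n{p.sequence}\n")
    pd.DataFrame(
        [
            {"gene": v.gene, "protein_id": v.protein_id, "mutation": v.label,
             "vaf": v.vaf}
            for v in cohort.genomics.variants
        ]
    ).to_csv(out / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": e.gene, "tpm": e.tpm} for e in cohort.genomics.expression]
    ).to_csv(out / "expression.tsv", sep="\t", index=False)
    cohort.genomics.truth.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    for sample in cohort.repertoire.blood_samples:
        write_clonotype_table(sample, out / f"{sample.label}.tsv")
    write_clonotype_table(cohort.repertoire.mutant_stim, out / "mutant_stim.tsv")
    write_clonotype_table(cohort.repertoire.wt_stim, out / "wt_stim.tsv")
    cohort.repertoire.truth.to_csv(out / "truth_responders.tsv", sep="\t", index=False)
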