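# Methods

## Variant application and peptide windowing

Variants are protein-level somatic mutations in HGVS-p short notation, with
1-based inclusive coordinates: substitutions (`A161T`), in-frame deletions
(`E746_A750del`, `K745del`) and in-frame insertions (`K745_E746insT`).
Frameshift (`fs`) and stop-gain (`*`) notations are rejected: their mutant
C-terminal sequence cannot be derived without nucleotide context, which the
pipeline deliberately does not consume. A multi-residue deletion label names
only its first and last residues; the full deleted string is resolved (and
validated) against the reference sequence when the variant is applied.

The mutation-centered window takes up to `flank = 10` wild-type residues on
each side of the mutated position, so a substitution away from the termini
yields a 21-mer with the substituted residue central. "Centered on the
mutated amino acid" is undefined for a deletion; the window is centered on
the deletion junction (10 residues each side, a 20-mer), which is the unique
choice that reproduces the two published exon-19-deletion junction peptides.
Insertions take the inserted block plus 10 residues each side. Windows
truncate at the protein termini.

Peptide enumeration slides 9-, 10- and 11-mers over the mutant window and
keeps those covering at least one mutation-derived residue (for deletions:
straddling the junction). Each mutant k-mer is paired with the equal-length
wild-type peptide starting at the same wild-type coordinate as the k-mer's
first residue (N-terminal coordinate anchoring — again the unique rule
consistent with the published junction pairs). Mutant k-mers that occur
anywhere in the source wild-type protein are self peptides and are dropped
(not only the paired counterpart: a deletion-window k-mer lying entirely in
one flank is wild-type). Output order is deterministic (k, then offset);
k-mers shorter than 9 are never emitted. The enumeration is tested against a
brute-force oracle (all k-mers of the mutant protein absent from the
wild-type protein) on random proteins.

The packaged reference contexts store the true 1-based protein coordinate of
their first residue in the FASTA header (`start=` key) so published variant
coordinates apply directly to short local excerpts; a neutral glycine-flank
padding helper serves tests needing full 21-mer windows. The VAF column of
the packaged variant table is synthetic (the source table prints none),
chosen under purity 0.6 to reproduce the published clonal/subclonal split;
the synthetic expression table likewise only encodes "these six genes are
expressed".

## MHC binding

The binding step is a contract: any map peptide → IC50 (nM) works. The
NetMHCpan-3.0 plain-text adapter maps columns by header tokens (`Peptide`,
`HLA`, `Aff(nM)`), skips banner lines, and keeps rows for all alleles.
Peptides absent from a supplied prediction table are treated as non-binders
(50000 nM), since external predictors routinely report only peptides below a
cutoff; the pipeline logs how many were defaulted.

The packaged stub predictor makes the pipeline fully deterministic without
external tools: score s = mean per-(residue, position) weight over the
peptide plus a small CRC32-derived per-allele offset, clipped to [0, 1], and
IC50 = 50000^(1−s) nM. The weight table was drawn once from Beta(2, 3)
(seeded, generation procedure documented in the repository history) and
frozen as package data; a golden-file test pins its outputs. Beta(2, 3)
centers scores near 0.4 so that roughly a third of random peptides fall
under 500 nM, mimicking the selectivity of a real predictor. The stub is a
test instrument, not a binding model: its IC50s carry no biology.

The binder filter keeps IC50 strictly below 500 nM (the conventional MHC-I
binder definition; 500.0 exactly is removed).

## Candidate selection

Expression filter: a candidate survives if its gene's TPM ≥ 1 (a common
transcript-detection floor; configurable), genes absent from the table count
as 0. Neoantigen expression is VAF × TPM, the simplest combination monotone
in both.

The composite selection score is a weighted sum (the source procedure names
its indexes and the "score > 0" rule but no functional form, so the form
here is the package's own documented choice):

    score = 2·(1 − log IC50 / log 50000) + 0.5·m + 0.5·VAF
          + 0.5·cleavage + 0.5·TAP + 0.5·min(1, log2(TPM+1)/10) − 1

with mutation-type code m = 1 for in-frame indels (fully tumor-specific
junction sequence) and 0.5 for substitutions. Cleavage and TAP are pluggable
predictor hooks with neutral 0.5 defaults — no re-implementation of those
models. The defaults satisfy, and a test enforces, the consistency
constraint that every published candidate peptide (all IC50 < 500 nM) scores
positive with neutral auxiliaries; a 50000 nM non-binder scores negative
even with favorable auxiliaries. Peptides from the same (gene, mutation)
group count as a single neoantigen.

## Burden and clonality

TMB = non-silent mutations / Mb of exome examined; TNB = neoantigens / Mb.
Class boundaries are inclusive toward the named class: high ⇔ TMB ≥ 10,
low ⇔ TMB ≤ 2.5, TNB high ⇔ TNB ≥ 4.5. The default exome footprint is 30 Mb
(whole-exome capture scale) and configurable; the source study's printed
mutation count, TMB and TNB cannot be jointly inverted to a single footprint,
so no attempt is made to reproduce its absolute TNB from counts — the
classification of the printed values is what is reproduced.

CCF = VAF·(ρ·CN + 2(1−ρ))/(ρ·m) with purity ρ an input (tumor-purity
estimation is upstream), CN = 2 and m = 1 by default (diploid heterozygous).
Clonal ⇔ CCF ≥ 0.8 (standard convention; configurable). Estimates above 1
are clipped to 1 with a warning (binomial sampling noise routinely overshoots
at moderate depth); estimates above 2 raise, since they indicate inconsistent
purity/copy-number inputs rather than noise. At depth 200 and purity 0.6 the
binomial standard error on the CCF scale is ≈ 0.1, so point recovery of CCF
within ±0.1 is only tested at higher depth, while the coarser clonal/subclonal
labels recover with ≥ 95% concordance at depth 200.

## TCR repertoire

Clone identity is (CDR3 nucleotide sequence, V, J) when the nucleotide CDR3
is present, else (CDR3 amino-acid sequence, V, J) — the strictest key the
input provides. Frequencies are always renormalized from counts; a stored
frequency column disagreeing by > 1e-6 triggers a warning and counts win.
High-frequency clones are those at frequency ≥ 10⁻³ (inclusive).

The stimulation screen encodes "comparing the frequency of each T-cell
clone" as the standard 2×2 table: clone reads vs all other reads, mutant-
vs wild-type-stimulated culture. The one-sided p is the upper-tail
hypergeometric probability P(X ≥ a) conditional on the margins (computed via
`scipy.stats.hypergeom.sf`; an exhaustive exact-integer enumeration oracle
covers every table with margins ≤ 30 in tests). The odds ratio is the
cross-product ratio with a Haldane–Anscombe 0.5 added to all cells only when
some cell is zero, and only for the odds ratio — the p-value always uses the
uncorrected table. A clone is significant iff OR > 10 and p < 0.01, both
strict, with no multiple-testing correction by default (mirroring the
stated criterion); Benjamini–Hochberg adjustment is available behind a flag.
The compound criterion is conservative: on null pairs the flagged fraction
is far below the nominal 1%.

Tracking classifies each significant clone against ordered blood samples:
persistent high-frequency (≥ 10⁻³ at baseline and ≥ 1 read at every later
timepoint), post-treatment-only (0 reads at baseline, detected later), else
other. "Detected" means ≥ 1 read. V–J usage sums clone frequencies per
(V, J) pair; entries sum to 1.

## Synthetic cohort

The generator emulates the study conditions and is fully determined by its
seed. Genomics: 84 non-silent mutations (42 clonal at CCF 1, 42 subclonal
with CCF ~ U(0.1, 0.5)), one per i.i.d.-uniform random protein of length
300; ~10% are in-frame deletions of 3–5 residues. Observed VAF is a binomial
draw at depth 200 around the purity-0.6 expected VAF. Gene expression is
LogNormal(1, 1.5) with 75% of genes set to 0 — emulating the observed
sparsity where only a minority of binder-mutation genes were transcribed.

Repertoire: 1000 clones with Zipf(α = 1.2) baseline frequencies (standard
power-law repertoire model), sampled multinomially at depth 10⁵ at baseline
and three post-treatment timepoints; background clones persist with
probability 0.9 per timepoint (vacated mass moves to a replacement clone of
new identity) with lognormal σ = 0.2 frequency jitter. Of 25 planted
responder clones, 18 are persistent (blood frequency 3 × 10⁻³ at every
timepoint) and 7 have exactly zero baseline weight, appearing after
treatment start. Stimulation cultures derive from the final PBMC pool with
each responder reset to culture frequency 10⁻³; the mutant culture
multiplies responder weights 20-fold before renormalization, the wild-type
culture does not. With these defaults each responder's expected odds ratio
is ≈ 13 (renormalization across 25 simultaneous expansions deflates the
naive 20), comfortably above the OR > 10 bar at depth 10⁵.

What the generator does not emulate: linkage between mutations (independent
genes only), real V(D)J recombination statistics (V/J labels from a small
fixed catalog, CDR3 strings random), sequencing error in clonotype calls,
clone-size drift between stimulation and blood compartments, and any true
immunology connecting the neoantigen arm to the TCR arm — responder clones
are planted, not derived from peptides. Passing tests therefore demonstrate
that the detection and classification machinery recovers planted structure
under realistic sampling noise, not that the pipeline's biological
predictions are correct on real patients.

## Numerical and design notes

- All thresholds are config keys (`PipelineConfig`), defaulting to the
  published values; the scoring weights and the m-encoding of mutation type
  are explicitly flagged as the package's own convention in the config
  docstring.
- Problem sizes in tests and analyses (50 null replicates × 200 clones,
  100 planted expansions in batches of 4, 84-variant cohorts) were chosen as
  the smallest sizes at which the binomial/hypergeometric guarantees being
  tested are statistically meaningful.
- Planting 100 simultaneous 20-fold expansions in one culture would deflate
  every odds ratio below 10 through renormalization alone; the power
  analysis therefore plants expansions in batches of 4 per replicate,
  keeping the per-clone condition (frequency 10⁻³, 20-fold, depth 10⁵)
  intact.
- Ties and boundaries: IC50 exactly 500 nM is not a binder; frequency
  exactly 10⁻³ is high-frequency; TMB exactly at a cutoff takes the named
  class; OR exactly 10 or p exactly 0.01 is not significant.
- Degenerate inputs: empty variant tables, empty clonotype tables and
  windows shorter than 9 residues yield empty outputs, not errors; zero
  purity, zero-read stimulation samples and malformed labels raise with
  stage-named messages.
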