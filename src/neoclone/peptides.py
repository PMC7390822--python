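"""Protein-level variant application and mutant/wild-type peptide enumeration.

This module turns a somatic protein variant (substitution or in-frame indel,
HGVS-p-style notation) into the set of MHC-I-length peptides that could only
exist in the mutant proteome: the variant is applied to the reference protein,
a mutation-centered context window is cut out (up to 10 flanking residues on
each side of the mutated residue, or of the deletion junction), and every
9-11-mer of that window that covers a mutation-derived position is emitted
together with its coordinate-matched wild-type counterpart.

Coordinates are 1-based inclusive throughout, following HGVS-p convention.
A :class:`ProteinRecord` may represent a local excerpt of a longer protein;
its ``start`` attribute holds the 1-based position of its first residue so
that published variant coordinates (e.g. EGFR E746) apply directly.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_FLANK = 10
DEFAULT_K_RANGE = (9, 10, 11)


class VariantParseError(ValueError):
    """Raised when an HGVS-p-style label cannot be parsed."""


class UnsupportedVariantError(ValueError):
    """Raised for variant classes outside scope (frameshift, stop-gain, splice)."""


class ReferenceMismatchError(ValueError):
    """Raised when a variant's reference residues disagree with the protein."""


class VariantKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein (or local excerpt) in 1-letter amino-acid code.

    ``start`` is the 1-based position, in the full protein, of the first
    residue of ``sequence`` (1 for a complete protein).
    """

    id: str
    sequence: str
    gene: str = ""
    start: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if self.start < 1:
            raise ValueError(f"protein {self.id!r}: start must be >= 1")

    @property
    def end(self) -> int:
        """1-based position of the last residue."""
        return self.start + len(self.sequence) - 1

    def local(self, pos: int) -> int:
        """Convert a 1-based protein position to a 0-based index in ``sequence``."""
        if not self.start <= pos <= self.end:
            raise IndexError(
                f"position {pos} outside record {self.id!r} "
                f"[{self.start}, {self.end}]"
            )
        return pos - self.start


@dataclass(frozen=True)
class ProteinVariant:
    """A protein-level somatic mutation.

    For multi-residue deletions parsed from a label such as ``E746_A750del``
    only the first and last deleted residues are known until the variant is
    checked against a sequence; ``ref_aa`` then holds the two endpoint
    residues and is completed by :func:`apply_protein_variant`.
    """

    kind: VariantKind
    start: int
    end: int
    ref_aa: str
    alt_aa: str
    gene: str = ""
    protein_id: str = ""
    vaf: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid variant span [{self.start}, {self.end}]")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        """HGVS-p-style label, round-tripping :func:`parse_variant_label`."""
        if self.kind is VariantKind.SUBSTITUTION:
            return f"{self.ref_aa}{self.start}{self.alt_aa}"
        if self.kind is VariantKind.INFRAME_DELETION:
            if self.start == self.end:
                return f"{self.ref_aa[0]}{self.start}del"
            return f"{self.ref_aa[0]}{self.start}_{self.ref_aa[-1]}{self.end}del"
        anchor, nxt = self.ref_aa[0], self.ref_aa[-1]
        return f"{anchor}{self.start}_{nxt}{self.start + 1}ins{self.alt_aa}"


_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DEL_RANGE_RE = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)del$")
_DEL_SINGLE_RE = re.compile(r"^([A-Z])(\d+)del$")
_INS_RE = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)ins([A-Z]+)$")


def parse_variant_label(label: str) -> ProteinVariant:
    """Parse an HGVS-p-style short label into a :class:`ProteinVariant`.

    Supported grammars: ``A161T`` (substitution), ``E746_A750del`` / ``K745del``
    (in-frame deletion), ``K745_E746insT`` (in-frame insertion). Frameshift
    (``fs``) and stop-gain (``*``) notations are rejected as unsupported.
    """
    label = label.strip()
    if "fs" in label:
        raise UnsupportedVariantError(f"frameshift variant {label!r} not supported")
    if "*" in label:
        raise UnsupportedVariantError(f"stop-gain variant {label!r} not supported")

    m = _SUB_RE.match(label)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        _check_residues(label, ref + alt)
        if ref == alt:
            raise VariantParseError(f"{label!r}: null variant (alt equals ref)")
        return ProteinVariant(VariantKind.SUBSTITUTION, pos, pos, ref, alt)

    m = _DEL_RANGE_RE.match(label)
    if m:
        first, start, last, end = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        _check_residues(label, first + last)
        if end <= start:
            raise VariantParseError(f"{label!r}: deletion end {end} <= start {start}")
        return ProteinVariant(VariantKind.INFRAME_DELETION, start, end, first + last, "")

    m = _DEL_SINGLE_RE.match(label)
    if m:
        ref, pos = m.group(1), int(m.group(2))
        _check_residues(label, ref)
        return ProteinVariant(VariantKind.INFRAME_DELETION, pos, pos, ref, "")

    m = _INS_RE.match(label)
    if m:
        anchor, pos, nxt, pos2, ins = (
            m.group(1), int(m.group(2)), m.group(3), int(m.group(4)), m.group(5),
        )
        _check_residues(label, anchor + nxt + ins)
        if pos2 != pos + 1:
            raise VariantParseError(
                f"{label!r}: insertion anchors {pos} and {pos2} not adjacent"
            )
        return ProteinVariant(VariantKind.INFRAME_INSERTION, pos, pos, anchor + nxt, ins)

    raise VariantParseError(f"cannot parse variant label {label!r}")


def _check_residues(label: str, residues: str) -> None:
    bad = set(residues) - STANDARD_AA
    if bad:
        raise VariantParseError(f"{label!r}: non-standard residue {sorted(bad)}")


def _resolve_ref(protein: ProteinRecord, variant: ProteinVariant) -> str:
    """Return the full reference residue string at the variant span, validating
    whatever part of it the variant already carries."""
    i, j = protein.local(variant.start), protein.local(variant.end)
    found = protein.sequence[i : j + 1]
    claimed = variant.ref_aa
    if variant.kind is VariantKind.INFRAME_INSERTION:
        # ref_aa holds the two flanking residues of the insertion site
        nxt = protein.sequence[i + 1] if i + 1 < len(protein.sequence) else ""
        if claimed and (claimed[0] != found or (nxt and claimed[-1] != nxt)):
            raise ReferenceMismatchError(
                f"{variant.label}: expected flank {claimed!r}, found "
                f"{found + nxt!r} at position {variant.start}"
            )
        return found
    pos_str = (
        str(variant.start)
        if variant.start == variant.end
        else f"{variant.start}-{variant.end}"
    )
    if claimed and len(claimed) == len(found):
        if claimed != found:
            raise ReferenceMismatchError(
                f"{variant.label}: expected {claimed!r}, found {found!r} "
                f"at position {pos_str}"
            )
    elif claimed:  # endpoint residues only (multi-residue deletion label)
        if claimed[0] != found[0] or claimed[-1] != found[-1]:
            raise ReferenceMismatchError(
                f"{variant.label}: expected endpoints {claimed[0]!r}..{claimed[-1]!r},"
                f" found {found[0]!r}..{found[-1]!r} at "
                f"positions {variant.start}-{variant.end}"
            )
    return found


def apply_protein_variant(protein: ProteinRecord, variant: ProteinVariant) -> str:
    """Apply ``variant`` to ``protein`` and return the mutant sequence.

    The returned string covers the same local excerpt as ``protein.sequence``;
    its length differs by ``len(alt) - len(ref)`` for indels.
    """
    ref = _resolve_ref(protein, variant)
    i, j = protein.local(variant.start), protein.local(variant.end)
    seq = protein.sequence
    if variant.kind is VariantKind.SUBSTITUTION:
        return seq[:i] + variant.alt_aa + seq[j + 1 :]
    if variant.kind is VariantKind.INFRAME_DELETION:
        return seq[:i] + seq[j + 1 :]
    # insertion after the anchor residue
    return seq[: i + 1] + variant.alt_aa + seq[i + 1 :]


@dataclass(frozen=True)
class MutantWindow:
    """Mutation-centered context window over the mutant protein.

    ``site_offsets`` holds the 0-based offsets of mutation-derived residues in
    ``mutant_context`` (substituted or inserted residues); for a deletion it is
    empty and ``junction`` gives the offset of the first residue downstream of
    the deletion junction (a peptide is mutation-specific iff it straddles it).
    ``wt_protein`` retains the full wild-type excerpt so that wild-type
    counterpart peptides extending past the window can be recovered, and so
    that mutant peptides occurring elsewhere in the wild-type sequence can be
    excluded as self peptides.
    """

    mutant_context: str
    wt_context: str
    wt_anchor: int
    site_offsets: tuple[int, ...]
    junction: int | None
    wt_protein: ProteinRecord
    variant: ProteinVariant

    def covers(self, start: int, k: int) -> bool:
        """Does the k-mer at 0-based ``start`` cover a mutation-specific position?"""
        if self.junction is not None:
            return start < self.junction < start + k
        return any(start <= o < start + k for o in self.site_offsets)


def extract_window(
    protein: ProteinRecord, variant: ProteinVariant, flank: int = DEFAULT_FLANK
) -> MutantWindow:
    """Cut the mutation-centered window out of the mutant protein.

    Substitution: up to ``flank`` residues each side of the substituted residue
    (a 21-mer away from the termini, truncated at them). In-frame deletion: up
    to ``flank`` residues each side of the deletion junction. Insertion: the
    inserted residues with up to ``flank`` residues each side.
    """
    variant = replace(variant, ref_aa=_resolve_ref(protein, variant))
    mutant = apply_protein_variant(protein, variant)
    i = protein.local(variant.start)  # 0-based, in wild-type coordinates

    if variant.kind is VariantKind.SUBSTITUTION:
        lo = max(0, i - flank)
        hi = min(len(mutant), i + flank + 1)
        ctx = mutant[lo:hi]
        wt_ctx = protein.sequence[lo:hi]
        return MutantWindow(
            mutant_context=ctx,
            wt_context=wt_ctx,
            wt_anchor=protein.start + lo,
            site_offsets=(i - lo,),
            junction=None,
            wt_protein=protein,
            variant=variant,
        )

    if variant.kind is VariantKind.INFRAME_DELETION:
        # in the mutant, the junction sits between indices i-1 and i
        lo = max(0, i - flank)
        hi = min(len(mutant), i + flank)
        ctx = mutant[lo:hi]
        wt_ctx = protein.sequence[lo : min(len(protein.sequence), hi + variant.span)]
        return MutantWindow(
            mutant_context=ctx,
            wt_context=wt_ctx,
            wt_anchor=protein.start + lo,
            site_offsets=(),
            junction=i - lo,
            wt_protein=protein,
            variant=variant,
        )

    # insertion: inserted block occupies mutant indices i+1 .. i+len(alt)
    n_ins = len(variant.alt_aa)
    lo = max(0, i + 1 - flank)
    hi = min(len(mutant), i + 1 + n_ins + flank)
    ctx = mutant[lo:hi]
    wt_ctx = protein.sequence[lo : min(len(protein.sequence), hi - n_ins)]
    return MutantWindow(
        mutant_context=ctx,
        wt_context=wt_ctx,
        wt_anchor=protein.start + lo,
        site_offsets=tuple(range(i + 1 - lo, i + 1 + n_ins - lo)),
        junction=None,
        wt_protein=protein,
        variant=variant,
    )


@dataclass(frozen=True)
class PeptidePair:
    """A mutant k-mer with its coordinate-matched wild-type counterpart."""

    mutant_seq: str
    wt_seq: str
    gene: str = ""
    variant_label: str = ""
    covers_mutation: bool = True

    def __post_init__(self) -> None:
        if len(self.mutant_seq) != len(self.wt_seq):
            raise ValueError("mutant and wild-type peptides must have equal length")

    @property
    def k(self) -> int:
        return len(self.mutant_seq)


def _wt_offset(window: MutantWindow, mut_off: int) -> int:
    """Wild-type local offset (0-based, from ``wt_anchor``) paired with a mutant
    context offset under N-terminal coordinate anchoring."""
    v = window.variant
    if v.kind is VariantKind.SUBSTITUTION:
        return mut_off
    if v.kind is VariantKind.INFRAME_DELETION:
        assert window.junction is not None
        return mut_off if mut_off < window.junction else mut_off + v.span
    # insertion: residues inside the inserted block anchor to the first
    # wild-type residue after the insertion site
    first_ins = window.site_offsets[0]
    n_ins = len(v.alt_aa)
    if mut_off < first_ins:
        return mut_off
    if mut_off < first_ins + n_ins:
        return first_ins
    return mut_off - n_ins


def enumerate_peptide_pairs(
    window: MutantWindow, k_range: Sequence[int] = DEFAULT_K_RANGE
) -> list[PeptidePair]:
    """Enumerate mutation-covering k-mers of the window with wild-type partners.

    Every k-mer of the mutant context that covers at least one
    mutation-specific position (or straddles the deletion junction) is emitted
    once per (sequence, k), in deterministic order (by k, then start offset).
    The wild-type partner is the equal-length wild-type k-mer starting at the
    same wild-type coordinate as the mutant k-mer's first residue. Mutant
    k-mers that occur anywhere in the wild-type protein are self peptides and
    are dropped, as are pairs whose wild-type partner would run past the
    available wild-type sequence.
    """
    wt_seq = window.wt_protein.sequence
    anchor0 = window.wt_anchor - window.wt_protein.start  # 0-based in wt_seq
    ctx = window.mutant_context
    pairs: list[PeptidePair] = []
    seen: set[str] = set()
    for k in sorted(k_range):
        for s in range(len(ctx) - k + 1):
            if not window.covers(s, k):
                continue
            mut_kmer = ctx[s : s + k]
            if mut_kmer in seen:
                continue
            w0 = anchor0 + _wt_offset(window, s)
            if w0 + k > len(wt_seq):
                continue
            wt_kmer = wt_seq[w0 : w0 + k]
            if mut_kmer in wt_seq:  # self peptide (includes mut_kmer == wt_kmer)
                continue
            seen.add(mut_kmer)
            pairs.append(
                PeptidePair(
                    mutant_seq=mut_kmer,
                    wt_seq=wt_kmer,
                    gene=window.variant.gene or window.wt_protein.gene,
                    variant_label=window.variant.label,
                )
            )
    return pairs


def peptide_pairs_for_variant(
    protein: ProteinRecord,
    variant: ProteinVariant,
    flank: int = DEFAULT_FLANK,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
) -> list[PeptidePair]:
    """Convenience: window extraction + pair enumeration in one call."""
    return enumerate_peptide_pairs(extract_window(protein, variant, flank), k_range)


# ---------------------------------------------------------------------------
# I/O


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    The record id is the first header token; ``gene=SYMBOL`` and ``start=N``
    keys in the description are honoured (``start`` marks the 1-based protein
    coordinate of the excerpt's first residue).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, start = "", 1
        for tok in rec.description.split()[1:]:
            if tok.startswith("gene="):
                gene = tok[5:]
            elif tok.startswith("start="):
                start = int(tok[6:])
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), gene=gene, start=start)
        )
    return records


def read_variant_table(path: str | Path) -> list[ProteinVariant]:
    """Read a somatic variant TSV with columns gene, protein_id, mutation, vaf."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "protein_id": str})
    required = {"gene", "protein_id", "mutation", "vaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path}: missing columns {sorted(missing)}")
    variants = []
    for row in df.itertuples(index=False):
        v = parse_variant_label(str(row.mutation))
        variants.append(
            replace(v, gene=row.gene, protein_id=row.protein_id, vaf=float(row.vaf))
        )
    return variants


def write_peptide_pairs(pairs: Iterable[PeptidePair], path: str | Path) -> None:
    """Write peptide pairs as TSV: gene, mutation, k, mutant_peptide, wt_peptide."""
    df = pd.DataFrame(
        [
            {
                "gene": p.gene,
                "mutation": p.variant_label,
                "k": p.k,
                "mutant_peptide": p.mutant_seq,
                "wt_peptide": p.wt_seq,
            }
            for p in pairs
        ],
        columns=["gene", "mutation", "k", "mutant_peptide", "wt_peptide"],
    )
    df.to_csv(path, sep="\t", index=False)


def pad_context(record: ProteinRecord, n: int = 10, residue: str = "G") -> ProteinRecord:
    """Pad a local context with a neutral flank of glycines on both sides,
    shifting ``start`` so variant coordinates remain valid. Intended for tests
    that need full-width 21-mer windows around a short packaged context."""
    return ProteinRecord(
        id=record.id,
        sequence=residue * n + record.sequence + residue * n,
        gene=record.gene,
        start=record.start - n,
    )
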