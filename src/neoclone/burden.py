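"""Tumor mutational/neoantigen burden and mutation clonality.

TMB is the number of non-silent somatic mutations per megabase of exome
examined (high >= 10, low <= 2.5 muts/Mb); TNB is neoantigens per megabase
(high >= 4.5 neos/Mb). Clonality is classified from the cancer cell fraction
(CCF) under the standard diploid model:

    CCF = VAF * (purity * CN + 2 * (1 - purity)) / (purity * multiplicity)

where purity is the tumor cell fraction of the sample, CN the local tumor
copy number and multiplicity the number of mutant copies per tumor cell. A
mutation with CCF >= 0.8 (configurable) is called clonal. Purity is an input;
copy number and multiplicity default to 2 and 1 (diploid heterozygous).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

TMB_HIGH_CUTOFF = 10.0
TMB_LOW_CUTOFF = 2.5
TNB_HIGH_CUTOFF = 4.5
CCF_CLONAL_THRESHOLD = 0.8
DEFAULT_EXOME_MB = 30.0


@dataclass(frozen=True)
class BurdenSummary:
    n_nonsilent: int
    exome_mb: float
    tmb: float
    tmb_class: str  # high | intermediate | low
    n_neoantigens: int
    tnb: float
    tnb_high: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass(frozen=True)
class CCFEstimate:
    vaf: float
    purity: float
    copy_number: int
    multiplicity: int
    ccf: float
    clonal: bool


def classify_tmb(
    tmb: float,
    high_cutoff: float = TMB_HIGH_CUTOFF,
    low_cutoff: float = TMB_LOW_CUTOFF,
) -> str:
    """high iff tmb >= high_cutoff, low iff tmb <= low_cutoff, else
    intermediate (cutoffs inclusive toward the named class)."""
    if tmb >= high_cutoff:
        return "high"
    if tmb <= low_cutoff:
        return "low"
    return "intermediate"


def classify_tnb(tnb: float, high_cutoff: float = TNB_HIGH_CUTOFF) -> bool:
    """True iff tnb >= high_cutoff (high TNB)."""
    return tnb >= high_cutoff


def compute_tmb(
    n_nonsilent: int,
    exome_mb: float,
    high_cutoff: float = TMB_HIGH_CUTOFF,
    low_cutoff: float = TMB_LOW_CUTOFF,
) -> tuple[float, str]:
    """TMB in muts/Mb with its class (see :func:`classify_tmb`)."""
    if exome_mb <= 0:
        raise ValueError(f"exome footprint must be positive, got {exome_mb} Mb")
    tmb = n_nonsilent / exome_mb
    return tmb, classify_tmb(tmb, high_cutoff, low_cutoff)


def compute_tnb(
    n_neoantigens: int, exome_mb: float, high_cutoff: float = TNB_HIGH_CUTOFF
) -> tuple[float, bool]:
    """TNB in neos/Mb; high iff tnb >= high_cutoff."""
    if exome_mb <= 0:
        raise ValueError(f"exome footprint must be positive, got {exome_mb} Mb")
    tnb = n_neoantigens / exome_mb
    return tnb, classify_tnb(tnb, high_cutoff)


def summarize_burden(
    n_nonsilent: int, n_neoantigens: int, exome_mb: float = DEFAULT_EXOME_MB
) -> BurdenSummary:
    tmb, tmb_class = compute_tmb(n_nonsilent, exome_mb)
    tnb, tnb_high = compute_tnb(n_neoantigens, exome_mb)
    return BurdenSummary(
        n_nonsilent=n_nonsilent,
        exome_mb=exome_mb,
        tmb=tmb,
        tmb_class=tmb_class,
        n_neoantigens=n_neoantigens,
        tnb=tnb,
        tnb_high=tnb_high,
    )


def estimate_ccf(
    vaf: float,
    purity: float,
    copy_number: int = 2,
    multiplicity: int = 1,
    clonal_threshold: float = CCF_CLONAL_THRESHOLD,
) -> CCFEstimate:
    """Cancer cell fraction from VAF under the purity/copy-number model.

    Estimates implying CCF > 1 (sampling noise or model misfit) are clipped to
    1 with a warning; estimates beyond twice 1 indicate grossly inconsistent
    purity/copy-number inputs and raise instead.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if copy_number < 1 or multiplicity < 1:
        raise ValueError("copy number and multiplicity must be positive integers")
    ccf = vaf * (purity * copy_number + 2.0 * (1.0 - purity)) / (purity * multiplicity)
    if ccf > 2.0:
        raise ValueError(
            f"vaf {vaf} implies ccf {ccf:.2f} >> 1 at purity {purity}; "
            "check purity/copy-number inputs"
        )
    if ccf > 1.0:
        warnings.warn(
            f"ccf {ccf:.3f} > 1 clipped to 1 (vaf {vaf}, purity {purity})",
            stacklevel=2,
        )
        ccf = 1.0
    return CCFEstimate(
        vaf=vaf,
        purity=purity,
        copy_number=copy_number,
        multiplicity=multiplicity,
        ccf=ccf,
        clonal=ccf >= clonal_threshold,
    )


def expected_vaf(
    ccf: float, purity: float, copy_number: int = 2, multiplicity: int = 1
) -> float:
    """Forward model: the VAF implied by a CCF (inverse of estimate_ccf)."""
    return ccf * purity * multiplicity / (purity * copy_number + 2.0 * (1.0 - purity))
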