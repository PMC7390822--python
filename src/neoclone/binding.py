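"""MHC class I binding predictions: external-predictor adapter, stub, filter.

The binding-affinity step of the pipeline is a contract, not a model: any
source of per-peptide IC50 values (nanomolar; lower = stronger binder)
satisfies it. Two sources are provided:

* :func:`parse_netmhcpan` reads NetMHCpan-3.0-style plain-text output, the
  external predictor used for the published affinities.
* :func:`predict_stub` is a deterministic surrogate predictor driven by a
  packaged per-(residue, position) weight table, so the whole pipeline runs
  and tests reproducibly with no external tool. The weight table was drawn
  once from a seeded Beta(2, 3) and frozen as package data; it is never
  regenerated at run time.

The binder filter applies the conventional IC50 < 500 nM cutoff (strict
inequality, matching the "IC50 <500 nM" binder definition).
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .peptides import STANDARD_AA

IC50_MAX_NM = 50000.0  # affinity at the weakest end of the predictor scale
BINDER_THRESHOLD_NM = 500.0

_ALLELE_RE = re.compile(r"^HLA-([ABC])\*?(\d{2}):?(\d{2})$")


@dataclass(frozen=True)
class HLAAllele:
    """A normalized 2-field MHC class I allele name, e.g. ``HLA-A*11:01``."""

    name: str

    def __post_init__(self) -> None:
        m = _ALLELE_RE.match(self.name.strip())
        if not m:
            raise ValueError(f"cannot normalize HLA allele {self.name!r}")
        object.__setattr__(self, "name", f"HLA-{m.group(1)}*{m.group(2)}:{m.group(3)}")

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class BindingPrediction:
    """Predicted peptide-MHC affinity in nM."""

    peptide: str
    allele: HLAAllele
    ic50_nm: float

    def __post_init__(self) -> None:
        if self.ic50_nm <= 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50_nm}")


def _load_weights() -> pd.DataFrame:
    with resources.files("neoclone.data").joinpath("stub_weights.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="residue")
    return df


_WEIGHTS: pd.DataFrame | None = None


def stub_weights() -> pd.DataFrame:
    """The packaged per-(residue, position) weight table (rows: 20 residues,
    columns pos1..pos11, values in [0, 1])."""
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = _load_weights()
    return _WEIGHTS


def _allele_shift(allele: HLAAllele) -> float:
    """Small deterministic per-allele score offset (CRC32-based, platform
    independent), so different alleles rank peptides differently."""
    return ((zlib.crc32(allele.name.encode()) % 1000) / 1000.0 - 0.5) * 0.1


def predict_stub(
    peptides: Sequence[str],
    allele: HLAAllele,
    weights: pd.DataFrame | None = None,
) -> list[BindingPrediction]:
    """Deterministic surrogate binding predictor.

    Score ``s`` is the mean packaged weight of each (residue, position) in the
    peptide plus a per-allele offset, clipped to [0, 1]; the affinity is
    ``ic50 = 50000 ** (1 - s)`` nM, so s = 1 gives 1 nM and s = 0 gives
    50000 nM. Identical input gives bit-identical output on any platform.
    """
    table = weights if weights is not None else stub_weights()
    shift = _allele_shift(allele)
    out = []
    for pep in peptides:
        if not 9 <= len(pep) <= 11:
            raise ValueError(f"peptide {pep!r}: length must be 9-11")
        bad = set(pep) - STANDARD_AA
        if bad:
            raise ValueError(f"peptide {pep!r}: non-standard residues {sorted(bad)}")
        s = sum(table.at[res, f"pos{i + 1}"] for i, res in enumerate(pep)) / len(pep)
        s = min(1.0, max(0.0, s + shift))
        out.append(BindingPrediction(pep, allele, IC50_MAX_NM ** (1.0 - s)))
    return out


def score_to_ic50(s: float) -> float:
    """Closed-form stub transform, exposed for tests: 50000**(1-s), s in [0,1]."""
    return IC50_MAX_NM ** (1.0 - min(1.0, max(0.0, s)))


def ic50_to_score(ic50_nm: float) -> float:
    """Inverse transform, 1 - log(ic50)/log(50000), clipped to [0, 1]."""
    return min(1.0, max(0.0, 1.0 - math.log(ic50_nm) / math.log(IC50_MAX_NM)))


def parse_netmhcpan(path: str | Path) -> list[BindingPrediction]:
    """Parse NetMHCpan-3.0-style plain-text output into predictions.

    The dialect: banner/comment lines start with ``#`` or ``-``; a header line
    contains ``Peptide`` and an affinity column named ``Aff(nM)`` (or any token
    starting with ``Aff``); data rows are whitespace-delimited with columns in
    header order. Rows for every allele in the file are returned.
    """
    header: list[str] | None = None
    idx: dict[str, int] = {}
    out: list[BindingPrediction] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("-"):
            continue
        toks = line.split()
        if header is None:
            if "Peptide" in toks and any(t.startswith("Aff") for t in toks):
                header = toks
                idx = {
                    "peptide": toks.index("Peptide"),
                    "allele": toks.index("HLA") if "HLA" in toks else 1,
                    "aff": next(i for i, t in enumerate(toks) if t.startswith("Aff")),
                }
            continue
        if toks[0] in {"Pos", "pos"} or line.startswith("Protein"):
            continue
        try:
            peptide = toks[idx["peptide"]]
            allele = HLAAllele(toks[idx["allele"]])
            aff = float(toks[idx["aff"]].replace(",", ""))
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: cannot parse NetMHCpan-3.0 dialect row {line!r}: {exc}"
            ) from exc
        out.append(BindingPrediction(peptide, allele, aff))
    if header is None and out == []:
        # empty file (or banner only) is an empty prediction set; a file with
        # data rows but no recognizable header is a dialect error
        text = Path(path).read_text().strip()
        if text and any(
            ln.strip() and not ln.lstrip().startswith(("#", "-"))
            for ln in text.splitlines()
        ):
            raise ValueError(
                f"{path}: no NetMHCpan-3.0 header line with Peptide/Aff(nM) columns"
            )
    return out


def binder_filter(
    predictions: Iterable[BindingPrediction],
    threshold_nm: float = BINDER_THRESHOLD_NM,
) -> list[BindingPrediction]:
    """Keep predictions with ic50 strictly below ``threshold_nm`` (stable order)."""
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    return [p for p in predictions if p.ic50_nm < threshold_nm]


def load_table1_affinities() -> pd.DataFrame:
    """The packaged transcription of the published 13 candidate peptide pairs
    with their predicted affinities; thousands separators are normalized."""
    with resources.files("neoclone.data").joinpath("table1_affinities.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", thousands=",")
    df["ic50_mut"] = df["ic50_mut"].astype(float)
    df["ic50_wt"] = df["ic50_wt"].astype(float)
    return df
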