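"""Pipeline configuration: every published threshold as a configurable key."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .selection import ScoreWeights


@dataclass
class PipelineConfig:
    """Thresholds and model parameters of the full pipeline.

    Defaults are the published values: IC50 < 500 nM binder cutoff, TMB
    cutoffs 10/2.5 muts/Mb, TNB cutoff 4.5 neos/Mb, high-frequency clone
    cutoff 1e-3, significant-clone criterion OR > 10 and p < 0.01. The
    remaining keys (expression floor, CCF clonality threshold, exome
    footprint, purity model) are the package's documented choices.
    """

    allele: str = "HLA-A*11:01"
    flank: int = 10
    k_min: int = 9
    k_max: int = 11
    binder_threshold_nm: float = 500.0
    tpm_min: float = 1.0
    exome_mb: float = 30.0
    purity: float = 0.6
    copy_number: int = 2
    multiplicity: int = 1
    ccf_clonal_threshold: float = 0.8
    tmb_high: float = 10.0
    tmb_low: float = 2.5
    tnb_high: float = 4.5
    hf_cutoff: float = 1e-3
    or_cutoff: float = 10.0
    p_cutoff: float = 0.01
    bh_correct: bool = False
    cleavage: float = 0.5
    tap: float = 0.5
    score_weights: ScoreWeights = field(default_factory=ScoreWeights)

    @property
    def k_range(self) -> tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "score_weights" in raw and isinstance(raw["score_weights"], dict):
            raw = dict(raw)
            raw["score_weights"] = ScoreWeights(**raw["score_weights"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
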