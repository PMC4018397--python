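"""Pipeline configuration: input paths, thresholds, seed, output directory.

Threshold defaults are the screening values the analysis uses throughout:
differential calling at FDR <= 0.001 with |log2 ratio| >= 1, the stricter
|log2 ratio| >= 3 cut for network integration, precursor filters
(MFE < -18 kcal/mol, MFEI > 0.85, mature length 16-30 nt, <= 10 genome
hits, 150 nt flanks), target-site penalty cutoff 4.0, and pathway
significance at P < 0.05 with FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .io import read_config_yaml


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "capmir_out"
    seed: int = 0

    # inputs
    mirna_counts: str | None = None
    mirna_totals: tuple[int, int] | None = None
    mrna_counts: str | None = None
    mrna_totals: tuple[int, int] | None = None
    mature_fasta: str | None = None
    genome_fasta: str | None = None
    hairpin_hits: str | None = None
    utr_fasta: str | None = None
    pathways_gmt: str | None = None
    qc_yaml: str | None = None
    categories: str | None = None

    # thresholds
    fdr_max: float = 0.001
    log2_min: float = 1.0
    integration_abs_log2: float = 3.0
    mfe_max: float = -18.0
    mfei_min: float = 0.85
    mature_len: tuple[int, int] = (16, 30)
    genome_hits_max: int = 10
    flank: int = 150
    target_max_penalty: float = 4.0
    enrich_p: float = 0.05
    enrich_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_max <= 1 or not 0 <= self.enrich_fdr <= 1:
            raise ValueError("FDR thresholds must lie in [0, 1]")
        if not 0 < self.enrich_p <= 1:
            raise ValueError("enrich_p must lie in (0, 1]")
        if self.log2_min < 0 or self.integration_abs_log2 < 0:
            raise ValueError("log2 thresholds must be non-negative")
        if self.mfe_max > 0:
            raise ValueError("mfe_max is an energy in kcal/mol, <= 0")
        if self.mfei_min < 0:
            raise ValueError("mfei_min must be non-negative")
        lo, hi = self.mature_len
        if not 1 <= lo <= hi:
            raise ValueError("mature_len range invalid")
        if self.genome_hits_max < 1 or self.flank < 0:
            raise ValueError("genome_hits_max >= 1 and flank >= 0 required")
        if self.target_max_penalty < 0:
            raise ValueError("target_max_penalty must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = read_config_yaml(path)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("mirna_totals", "mrna_totals", "mature_len"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
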