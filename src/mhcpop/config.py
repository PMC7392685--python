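"""Pipeline configuration: locus definitions, thresholds, paths, seed.

Serializes to/from YAML losslessly.  Thresholds default to the amplicon-ratio
calling constants (homozygote 0.10, heterozygote band from 0.35, merged-read
floor 290 bp, minimum-allele-frequency numerator 5).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

__all__ = ["LocusConfig", "PipelineConfig"]


@dataclass
class LocusConfig:
    name: str
    fwd_primer: str
    rev_primer: str
    amplicon_length: int  # post-trim length
    min_merged_length: int = 290
    exon: Optional[tuple[int, int]] = None  # 0-based half-open, within the amplicon

    def __post_init__(self) -> None:
        if self.exon is not None:
            self.exon = tuple(self.exon)
            s, e = self.exon
            if not (0 <= s < e <= self.amplicon_length):
                raise ValueError(f"{self.name}: exon {self.exon} outside amplicon of {self.amplicon_length} bp")


@dataclass
class PipelineConfig:
    loci: list[LocusConfig]
    seed: int = 0
    homo_threshold: float = 0.10
    het_low_threshold: float = 0.35
    maf_numerator: int = 5
    primer_max_mismatch: int = 0
    n_individuals: int = 200
    n_founders: int = 60
    n_generations: int = 2
    out_dir: str = "results/pipeline"
    cohort_column: str = "cohort"

    def __post_init__(self) -> None:
        if not 0 < self.homo_threshold < self.het_low_threshold <= 0.5:
            raise ValueError("thresholds must satisfy 0 < homo < het_low <= 0.5")
        self.loci = [LocusConfig(**l) if isinstance(l, dict) else l for l in self.loci]

    def locus(self, name: str) -> LocusConfig:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        elif isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**data)


def default_pipeline_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Two-locus defaults mirroring the study template: a 250 bp classical
    locus and a 360 bp non-classical locus whose 270 bp exon sits at offset 45."""
    from .simulate import DEFAULT_PRIMERS

    loci = [
        LocusConfig(
            name="DRB",
            fwd_primer=DEFAULT_PRIMERS["DRB"][0],
            rev_primer=DEFAULT_PRIMERS["DRB"][1],
            amplicon_length=250,
            min_merged_length=290,
        ),
        LocusConfig(
            name="DOB",
            fwd_primer=DEFAULT_PRIMERS["DOB"][0],
            rev_primer=DEFAULT_PRIMERS["DOB"][1],
            amplicon_length=360,
            min_merged_length=290,
            exon=(45, 315),
        ),
    ]
    return PipelineConfig(loci=loci, seed=seed, **overrides)
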