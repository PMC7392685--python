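"""Shared domain types for amplicon MHC genotyping.

The pipeline treats each gene (e.g. the classical, antigen-presenting DRB and
the non-classical antigen-loading DOB of cervids) as a single autosomal diploid
locus whose alleles are distinct amplicon haplotype sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

__all__ = [
    "AlleleSequence",
    "PopulationSample",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (gap and N aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlleleSequence:
    """A named allele at a locus.

    ``exon`` is an optional 0-based half-open subinterval marking the coding
    exon within an extended amplicon (e.g. a 270 bp exon inside a 360 bp
    amplicon); statistics can be run on either the full sequence or the exon.
    """

    name: str
    seq: str
    exon: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.exon is not None:
            s, e = self.exon
            if not (0 <= s < e <= len(self.seq)):
                raise ValueError(f"exon interval {self.exon} outside sequence of length {len(self.seq)}")

    def exon_seq(self) -> str:
        if self.exon is None:
            return self.seq
        return self.seq[self.exon[0] : self.exon[1]]

    def translate(self, frame_offset: int = 0) -> str:
        """Standard-code translation of the (exon) sequence from ``frame_offset``."""
        nt = self.exon_seq()[frame_offset:]
        nt = nt[: len(nt) - len(nt) % 3]
        return str(Seq(nt).translate())


@dataclass
class PopulationSample:
    """Diploid genotypes for a set of individuals at one or two loci.

    ``genotypes[individual][locus]`` is an ordered pair of allele names (the
    pair is stored sorted so homozygotes read (a, a)).  ``cohorts`` carries
    population labels such as "founding" vs "2016"; membership is an input,
    never inferred.
    """

    loci: list[str]
    individuals: list[str]
    genotypes: dict[str, dict[str, tuple[str, str]]]
    cohorts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.individuals:
            if ind not in self.genotypes:
                raise ValueError(f"individual {ind!r} has no genotype entry")

    def genotype(self, individual: str, locus: str) -> tuple[str, str]:
        return self.genotypes[individual][locus]

    def subset(self, individuals: list[str]) -> "PopulationSample":
        return PopulationSample(
            loci=list(self.loci),
            individuals=list(individuals),
            genotypes={i: self.genotypes[i] for i in individuals},
            cohorts={i: c for i, c in self.cohorts.items() if i in set(individuals)},
        )

    def cohort(self, label: str) -> "PopulationSample":
        keep = [i for i in self.individuals if self.cohorts.get(i) == label]
        return self.subset(keep)
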