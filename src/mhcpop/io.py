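"""File formats: FASTA/FASTQ readers and writers, CSV tables, exon extraction.

All coordinates are 0-based, half-open.  Writers and readers round-trip
losslessly.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import AllelePanel, GenotypeCall, PanelEntry
from .core import AlleleSequence
from .read_filter import RankedVariantTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_variant_table",
    "read_variant_table",
    "write_calls",
    "read_calls",
    "write_panel",
    "read_panel",
    "read_pedigree",
    "write_pedigree",
    "extract_exon",
]


def read_fasta(path) -> list[AlleleSequence]:
    return [AlleleSequence(name=r.id, seq=str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(alleles: Iterable[AlleleSequence], path) -> None:
    records = [SeqRecord(Seq(a.seq), id=a.name, description="") for a in alleles]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[str]:
    """Read merged amplicon reads from FASTQ or FASTA (by extension)."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [str(r.seq).upper() for r in SeqIO.parse(str(path), fmt)]


def write_variant_table(table: RankedVariantTable, path) -> None:
    df = pd.DataFrame(
        {
            "rank": range(1, len(table) + 1),
            "sequence": table.sequences,
            "count": table.counts,
        }
    )
    df.insert(0, "individual", table.individual_id)
    df.insert(1, "locus", table.locus)
    df.to_csv(path, index=False)


def read_variant_table(path) -> RankedVariantTable:
    df = pd.read_csv(path)
    ind = str(df["individual"].iloc[0]) if len(df) else ""
    locus = str(df["locus"].iloc[0]) if len(df) and "locus" in df else ""
    rows = [(str(r["sequence"]), int(r["count"])) for _, r in df.iterrows()]
    return RankedVariantTable(individual_id=ind, locus=locus, rows=rows)


def write_calls(calls: Iterable[GenotypeCall], path) -> None:
    pd.DataFrame(
        [
            {
                "individual": c.individual_id,
                "locus": c.locus,
                "allele_1": c.allele_1 or "",
                "allele_2": c.allele_2 or "",
                "status": c.status,
                "top2_ratio": c.top2_ratio,
                "resolution_source": c.resolution_source,
            }
            for c in calls
        ]
    ).to_csv(path, index=False)


def read_calls(path) -> list[GenotypeCall]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        GenotypeCall(
            individual_id=str(r["individual"]),
            locus=str(r["locus"]),
            allele_1=str(r["allele_1"]) or None,
            allele_2=str(r["allele_2"]) or None,
            status=str(r["status"]),
            top2_ratio=float(r["top2_ratio"]),
            resolution_source=str(r["resolution_source"]),
        )
        for _, r in df.iterrows()
    ]


def write_panel(panel: AllelePanel, fasta_path, csv_path: Optional[str] = None) -> None:
    write_fasta([AlleleSequence(e.name, e.seq) for e in panel.entries], fasta_path)
    if csv_path:
        pd.DataFrame(
            [
                {
                    "name": e.name,
                    "validated": e.validated,
                    "population_frequency": e.population_frequency,
                }
                for e in panel.entries
            ]
        ).to_csv(csv_path, index=False)


def read_panel(fasta_path, csv_path: Optional[str] = None, locus: str = "") -> AllelePanel:
    alleles = read_fasta(fasta_path)
    meta = {}
    if csv_path and os.path.exists(str(csv_path)):
        df = pd.read_csv(csv_path)
        meta = {str(r["name"]): r for _, r in df.iterrows()}
    entries = []
    for a in alleles:
        m = meta.get(a.name)
        entries.append(
            PanelEntry(
                name=a.name,
                seq=a.seq,
                validated=bool(m["validated"]) if m is not None else False,
                population_frequency=float(m["population_frequency"]) if m is not None else 0.0,
            )
        )
    return AllelePanel(locus=locus, entries=entries)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    need = {"individual", "sire", "dam"}
    if not need <= set(df.columns):
        raise ValueError(f"pedigree CSV must have columns {sorted(need)}")
    return df[["individual", "sire", "dam"] + [c for c in df.columns if c not in need]]


def write_pedigree(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def extract_exon(
    panel: AllelePanel, interval: tuple[int, int], suffix: str = "_exon2"
) -> tuple[AllelePanel, dict[str, list[str]]]:
    """Extract a 0-based half-open subinterval from every panel allele and
    collapse identical sub-sequences.

    Collapsed alleles get a combined name in the shared-serial style (e.g.
    three extended alleles *01, *02 and *11 sharing one exon become
    ``*010211<suffix>``).  Returns the exon panel and a map exon-name ->
    contributing extended allele names.
    """
    s, e = interval
    if s < 0 or s >= e:
        raise ValueError(f"bad interval {interval}")
    for entry in panel.entries:
        if e > len(entry.seq):
            raise ValueError(f"interval {interval} out of bounds for {entry.name} (len {len(entry.seq)})")
    groups: dict[str, list[PanelEntry]] = {}
    for entry in panel.entries:
        groups.setdefault(entry.seq[s:e], []).append(entry)

    def exon_name(members: list[PanelEntry]) -> str:
        from .caller import _serial

        serials = [_serial(m.name) for m in members]
        base = members[0].name
        prefix = base[: base.rfind("*") + 1] if "*" in base else base + "*"
        if all(x is not None for x in serials):
            return prefix + "".join(f"{x:02d}" for x in sorted(serials)) + suffix
        return "+".join(m.name for m in members) + suffix

    entries, mapping = [], {}
    for seq, members in groups.items():
        name = exon_name(members)
        entries.append(
            PanelEntry(
                name=name,
                seq=seq,
                validated=any(m.validated for m in members),
                population_frequency=sum(m.population_frequency for m in members),
            )
        )
        mapping[name] = [m.name for m in members]
    return AllelePanel(locus=panel.locus + suffix, entries=entries), mapping
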