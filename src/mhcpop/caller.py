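"""Ratio-threshold diploid allele calling with chimera, frequency and pedigree filters.

The calling rule follows the amplicon-ratio convention: with c1, c2 the two
highest variant counts in an individual and r = c2/(c1+c2),

* r < 0.10            -> homozygote  (the "90:10" rule; typical homozygote noise ~99:1)
* 0.10 <= r < 0.35    -> ambiguous   (resolved by pedigree / external validation)
* 0.35 <= r <= 0.50   -> heterozygote (the "50:50 to 65:35" band; typical balance ~58:42)

Ambiguous calls are resolved against a validated allele panel plus pedigree
Mendelian consistency or an external (e.g. Sanger) validation flag; lower-rank
sequences are screened as single-crossover PCR chimeras; alleles below the
population minimum-allele-frequency threshold 5/(2n) are removed unless
independently validated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .core import PopulationSample
from .read_filter import RankedVariantTable

__all__ = [
    "Thresholds",
    "GenotypeCall",
    "PanelEntry",
    "AllelePanel",
    "classify_individual",
    "detect_chimera",
    "ChimeraHit",
    "resolve_ambiguous",
    "apply_maf_filter",
    "assign_nomenclature",
    "mendelian_consistency",
    "genotype_population",
]


@dataclass(frozen=True)
class Thresholds:
    homo: float = 0.10
    het_low: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.homo < self.het_low <= 0.5:
            raise ValueError("require 0 < homo < het_low <= 0.5")


@dataclass
class GenotypeCall:
    individual_id: str
    locus: str
    allele_1: Optional[str]  # sequence or assigned name
    allele_2: Optional[str]
    status: str  # homozygote | heterozygote | ambiguous | unresolved
    top2_ratio: float  # share of the second sequence among the top two; 0 if single variant
    resolution_source: str = "ratio"  # ratio | pedigree | external | none
    second_seq: Optional[str] = None  # retained for ambiguous calls pending resolution

    def alleles(self) -> tuple[str, str]:
        if self.allele_1 is None or self.allele_2 is None:
            raise ValueError(f"call for {self.individual_id} has no resolved genotype")
        return tuple(sorted((self.allele_1, self.allele_2)))


@dataclass
class PanelEntry:
    name: str
    seq: str
    validated: bool = False
    population_frequency: float = 0.0


@dataclass
class AllelePanel:
    locus: str
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate allele names in panel")
        seqs = [e.seq for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate allele sequences in panel")

    def by_seq(self) -> dict[str, PanelEntry]:
        return {e.seq: e for e in self.entries}

    def by_name(self) -> dict[str, PanelEntry]:
        return {e.name: e for e in self.entries}

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


# ---------------------------------------------------------------------------
# classification


def classify_individual(table: RankedVariantTable, thresholds: Thresholds = Thresholds()) -> GenotypeCall:
    """Call homozygote/heterozygote/ambiguous from the top-two variant counts.

    The ratio is the second count's share of the top two, so the printed
    "90:10" and "65:35" ratios map to thresholds 0.10 and 0.35 directly.
    Scale-invariant by construction.  An empty table yields an unresolved call.
    """
    if len(table) == 0:
        return GenotypeCall(table.individual_id, table.locus, None, None, "unresolved", 0.0, "none")
    if len(table) == 1:
        seq = table.sequences[0]
        return GenotypeCall(table.individual_id, table.locus, seq, seq, "homozygote", 0.0)
    c1, c2 = table.counts[0], table.counts[1]
    s1, s2 = table.sequences[0], table.sequences[1]
    ratio = c2 / (c1 + c2)
    if ratio < thresholds.homo:
        return GenotypeCall(table.individual_id, table.locus, s1, s1, "homozygote", ratio)
    if ratio >= thresholds.het_low:
        return GenotypeCall(table.individual_id, table.locus, s1, s2, "heterozygote", ratio)
    return GenotypeCall(
        table.individual_id, table.locus, s1, None, "ambiguous", ratio, second_seq=s2
    )


# ---------------------------------------------------------------------------
# chimera detection


@dataclass(frozen=True)
class ChimeraHit:
    is_chimera: bool
    interval: Optional[tuple[int, int]] = None  # half-open range of compatible crossover points


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def detect_chimera(candidate: str, parent_a: str, parent_b: str) -> ChimeraHit:
    """Test whether ``candidate`` is a single-crossover recombinant of the two
    parent sequences, i.e. prefix(a)+suffix(b) or prefix(b)+suffix(a) for some
    internal split point.  Returns the maximal compatible crossover interval
    (union over both orientations).  Gap-free, equal-length comparison.
    """
    L = len(candidate)
    if len(parent_a) != L or len(parent_b) != L:
        raise ValueError("chimera detection requires equal-length, gap-free sequences")
    if candidate == parent_a or candidate == parent_b:
        raise ValueError("candidate identical to a parent is not a chimera")

    lo, hi = None, None
    for first, second in ((parent_a, parent_b), (parent_b, parent_a)):
        pre = _common_prefix(candidate, first)
        suf = _common_prefix(candidate[::-1], second[::-1])
        k_min, k_max = max(1, L - suf), min(pre, L - 1)
        if k_min <= k_max:
            lo = k_min if lo is None else min(lo, k_min)
            hi = k_max if hi is None else max(hi, k_max)
    if lo is None:
        return ChimeraHit(False, None)
    return ChimeraHit(True, (lo, hi + 1))


def _is_panel_chimera(seq: str, top_seq: str, panel_seqs: Iterable[str]) -> bool:
    """Chimera screen for a rejected second sequence: recombinant of the
    individual's top sequence with any panel allele, or of any two panel
    alleles, of matching length."""
    pool = [s for s in set(panel_seqs) | {top_seq} if len(s) == len(seq) and s != seq]
    for i, a in enumerate(pool):
        for b in pool[i + 1:]:
            if detect_chimera(seq, a, b).is_chimera:
                return True
    return False


# ---------------------------------------------------------------------------
# pedigree consistency


def _consistent_with_parents(
    geno: tuple[str, str],
    sire_geno: Optional[tuple[str, str]],
    dam_geno: Optional[tuple[str, str]],
) -> bool:
    """Bipartite transmission check: one allele attributable to each assigned
    parent simultaneously.  An unknown parent acts as a wildcard."""
    a, b = geno
    for x, y in ((a, b), (b, a)):
        ok_s = sire_geno is None or x in sire_geno
        ok_d = dam_geno is None or y in dam_geno
        if ok_s and ok_d:
            return True
    return False


def _check_acyclic(pedigree: pd.DataFrame) -> None:
    parents = {
        r["individual"]: [p for p in (r["sire"], r["dam"]) if p]
        for _, r in pedigree.iterrows()
    }
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 1:
            raise ValueError(f"cyclic pedigree at {node!r}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for p in parents.get(node, []):
            visit(p)
        state[node] = 2

    for ind in parents:
        visit(ind)


def mendelian_consistency(
    sample: PopulationSample,
    pedigree: pd.DataFrame,
    locus: Optional[str] = None,
) -> tuple[dict[str, bool], float]:
    """Flag each offspring with assigned parents as Mendelian-consistent or not;
    return the per-individual flags and the consistent fraction over checked
    offspring (NaN when nothing is checkable)."""
    _check_acyclic(pedigree)
    loci = [locus] if locus else sample.loci
    known = set(sample.individuals)
    flags: dict[str, bool] = {}
    for _, row in pedigree.iterrows():
        ind, sire, dam = row["individual"], row["sire"], row["dam"]
        if ind not in known or (not sire and not dam):
            continue
        for p in (sire, dam):
            if p and p not in known:
                raise ValueError(f"pedigree references unknown individual {p!r}")
        ok = True
        for loc in loci:
            geno = sample.genotypes[ind].get(loc)
            if geno is None:
                continue
            sg = sample.genotypes[sire].get(loc) if sire else None
            dg = sample.genotypes[dam].get(loc) if dam else None
            ok = ok and _consistent_with_parents(geno, sg, dg)
        flags[ind] = ok
    frac = sum(flags.values()) / len(flags) if flags else float("nan")
    return flags, frac


# ---------------------------------------------------------------------------
# ambiguity resolution


def resolve_ambiguous(
    call: GenotypeCall,
    panel: AllelePanel,
    pedigree: Optional[pd.DataFrame] = None,
    external: Iterable[str] = (),
    parent_calls: Optional[dict[str, tuple[str, str]]] = None,
) -> GenotypeCall:
    """Resolve an ambiguous-band call (second share in [0.10, 0.35)).

    Upgrade to heterozygote when the second sequence matches a validated panel
    allele and the implied genotype is Mendelian-consistent with the assigned
    parents' calls, or when an external validation flag covers the individual.
    Downgrade to homozygote when the second sequence is a detected chimera of
    panel alleles.  Otherwise (no evidence either way) leave unresolved.

    ``parent_calls`` maps parent individual -> called genotype (sequence pair);
    parents absent from it are treated as unavailable.
    """
    if call.status != "ambiguous":
        raise ValueError("resolve_ambiguous expects an ambiguous call")
    second = call.second_seq
    by_seq = panel.by_seq()
    entry = by_seq.get(second) if second else None

    if call.individual_id in set(external):
        if entry is not None:
            return replace(
                call, allele_2=second, status="heterozygote", resolution_source="external", second_seq=None
            )
        # external validation asserts homozygosity when the second sequence is
        # not a known allele
        return replace(call, allele_2=call.allele_1, status="homozygote", resolution_source="external")

    if entry is not None and entry.validated and pedigree is not None and parent_calls is not None:
        row = pedigree.loc[pedigree["individual"] == call.individual_id]
        if len(row):
            sire = row.iloc[0]["sire"]
            dam = row.iloc[0]["dam"]
            sg = parent_calls.get(sire) if sire else None
            dg = parent_calls.get(dam) if dam else None
            if (sire or dam) and (sg is not None or dg is not None):
                if _consistent_with_parents((call.allele_1, second), sg, dg):
                    return replace(
                        call, allele_2=second, status="heterozygote",
                        resolution_source="pedigree", second_seq=None,
                    )

    if second is not None and entry is None:
        panel_seqs = [e.seq for e in panel.entries]
        if _is_panel_chimera(second, call.allele_1, panel_seqs):
            # a PCR recombinant of true alleles: the individual is homozygous
            # for its leading sequence
            return replace(call, allele_2=call.allele_1, status="homozygote", resolution_source="ratio")
    return replace(call, status="unresolved", resolution_source="none")


# ---------------------------------------------------------------------------
# population MAF filter and nomenclature


def apply_maf_filter(
    panel: AllelePanel,
    n_individuals: int,
    calls: Optional[list[GenotypeCall]] = None,
    numerator: int = 5,
) -> tuple[AllelePanel, list[str], float]:
    """Remove unvalidated alleles whose population frequency falls below
    ``numerator / (2 n)`` (the minimum five-copies rule); validated alleles are
    retained regardless.  Individuals whose call includes a removed allele are
    flagged for exclusion.  Idempotent.  Returns (panel, flagged, threshold)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    threshold = numerator / (2 * n_individuals)
    removed = {
        e.name for e in panel.entries if not e.validated and e.population_frequency < threshold
    }
    kept = [e for e in panel.entries if e.name not in removed]
    flagged: list[str] = []
    if calls and removed:
        removed_seqs = {e.seq for e in panel.entries if e.name in removed}
        for c in calls:
            if c.allele_1 in removed_seqs or c.allele_1 in removed or (
                c.allele_2 in removed_seqs or c.allele_2 in removed
            ):
                flagged.append(c.individual_id)
    return AllelePanel(locus=panel.locus, entries=kept), flagged, threshold


def _serial(name: str) -> Optional[int]:
    import re

    m = re.search(r"\*(\d+)\s*$", name)
    return int(m.group(1)) if m else None


def assign_nomenclature(
    candidate_seqs: list[str],
    known: AllelePanel,
    prefix: Optional[str] = None,
) -> dict[str, str]:
    """Map candidate sequences to allele names: exact matches to known alleles
    reuse the existing name; novel sequences get consecutive serial numbers
    continuing after the highest known serial, in the given candidate order."""
    names = [e.name for e in known.entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate names in known panel")
    by_seq = {e.seq: e.name for e in known.entries}
    serials = [s for s in (_serial(n) for n in names) if s is not None]
    next_serial = (max(serials) + 1) if serials else 1
    if prefix is None:
        if names:
            base = names[0]
            prefix = base[: base.rfind("*") + 1] if "*" in base else base + "*"
        else:
            prefix = "ALLELE*"
    mapping: dict[str, str] = {}
    for seq in candidate_seqs:
        if seq in mapping:
            continue
        if seq in by_seq:
            mapping[seq] = by_seq[seq]
        else:
            mapping[seq] = f"{prefix}{next_serial:02d}"
            next_serial += 1
    return mapping


# ---------------------------------------------------------------------------
# population-level orchestration


def genotype_population(
    tables: list[RankedVariantTable],
    known: Optional[AllelePanel] = None,
    pedigree: Optional[pd.DataFrame] = None,
    external: Iterable[str] = (),
    thresholds: Thresholds = Thresholds(),
    locus: str = "",
    maf_numerator: int = 5,
    external_genotypes: Optional[dict[str, tuple[str, str]]] = None,
) -> tuple[list[GenotypeCall], AllelePanel, dict]:
    """Full calling procedure for one locus.

    1. Ratio-classify every individual from its ranked variant table.
    2. Build the candidate allele panel from resolved calls; screen candidate
       sequences that are single-crossover chimeras of two panel alleles.
    3. Resolve ambiguous calls in pedigree order (parents first) using the
       validated panel, Mendelian consistency, and external validation flags.
    4. Apply the population minimum-allele-frequency filter once, flagging
       individuals whose only support is a removed allele.
    5. Assign nomenclature (known names reused, novel sequences serialised).

    Returns (final calls with allele *names*, final panel, report dict).
    """
    known = known or AllelePanel(locus=locus)
    calls = {t.individual_id: classify_individual(t, thresholds) for t in tables}
    tables_by_id = {t.individual_id: t for t in tables}

    # independently determined genotypes (e.g. Sanger-sequenced individuals)
    # take precedence over the read-ratio call
    for ind, pair in (external_genotypes or {}).items():
        if ind not in calls:
            continue
        a, b = sorted(pair)
        calls[ind] = GenotypeCall(
            individual_id=ind, locus=locus, allele_1=a, allele_2=b,
            status="homozygote" if a == b else "heterozygote",
            top2_ratio=calls[ind].top2_ratio, resolution_source="external",
        )

    # candidate panel from resolved calls
    seq_copies: Counter = Counter()
    for c in calls.values():
        if c.status == "homozygote":
            seq_copies[c.allele_1] += 2
        elif c.status == "heterozygote":
            seq_copies[c.allele_1] += 1
            seq_copies[c.allele_2] += 1
    # chimera screen on candidates: drop any candidate explainable as a
    # recombinant of two more frequent candidates
    ranked = [s for s, _ in seq_copies.most_common()]
    panel_seqs: list[str] = []
    for s in ranked:
        if not _is_panel_chimera(s, s, [p for p in panel_seqs if len(p) == len(s)]):
            panel_seqs.append(s)

    order = sorted(panel_seqs, key=lambda s: (-seq_copies[s], s))
    naming = assign_nomenclature(order, known)
    total_copies = sum(seq_copies[s] for s in panel_seqs) or 1
    known_by_seq = known.by_seq()

    # validation evidence, mirroring the Sanger/pedigree procedure: an allele
    # is validated when it matches a known reference, occurs in the resolved
    # call of an externally validated individual, or shows parent-offspring
    # transmission in the pedigree
    external = set(external)
    validated_seqs = set(known_by_seq)
    resolved_geno = {
        c.individual_id: (c.allele_1, c.allele_2)
        for c in calls.values()
        if c.status in ("homozygote", "heterozygote")
    }
    for ind in external:
        if ind in resolved_geno:
            validated_seqs.update(resolved_geno[ind])
    if pedigree is not None:
        for _, r in pedigree.iterrows():
            off = r["individual"]
            if off not in resolved_geno:
                continue
            for par in (r["sire"], r["dam"]):
                if par and par in resolved_geno:
                    validated_seqs.update(set(resolved_geno[off]) & set(resolved_geno[par]))

    entries = [
        PanelEntry(
            name=naming[s],
            seq=s,
            validated=s in validated_seqs,
            population_frequency=seq_copies[s] / total_copies,
        )
        for s in order
    ]
    panel = AllelePanel(locus=locus, entries=entries)

    # resolve ambiguous calls, parents before offspring
    if pedigree is not None:
        _check_acyclic(pedigree)
        ped_order: list[str] = []
        seen: set[str] = set()
        parents_of = {
            r["individual"]: [p for p in (r["sire"], r["dam"]) if p] for _, r in pedigree.iterrows()
        }

        def add(node: str) -> None:
            if node in seen:
                return
            seen.add(node)
            for p in parents_of.get(node, []):
                add(p)
            ped_order.append(node)

        for ind in calls:
            add(ind)
        ordering = [i for i in ped_order if i in calls]
    else:
        ordering = list(calls)

    parent_calls = dict(resolved_geno)
    n_ambiguous = sum(1 for c in calls.values() if c.status == "ambiguous")

    # pass 1: externally validated individuals (the Sanger-confirmed genotypes);
    # alleles they carry become validated panel entries before pedigree
    # resolution, as external confirmation validates the allele itself
    for ind in ordering:
        c = calls[ind]
        if c.status != "ambiguous" or ind not in external:
            continue
        resolved = resolve_ambiguous(c, panel, pedigree, external, parent_calls)
        calls[ind] = resolved
        if resolved.status in ("homozygote", "heterozygote"):
            parent_calls[ind] = (resolved.allele_1, resolved.allele_2)
            validated_seqs.update(parent_calls[ind])
    for e in panel.entries:
        if e.seq in validated_seqs:
            e.validated = True

    # pass 2: pedigree-informed resolution, parents before offspring
    for ind in ordering:
        c = calls[ind]
        if c.status != "ambiguous":
            continue
        resolved = resolve_ambiguous(c, panel, pedigree, external, parent_calls)
        calls[ind] = resolved
        if resolved.status in ("homozygote", "heterozygote"):
            parent_calls[ind] = (resolved.allele_1, resolved.allele_2)

    resolved_calls = [c for c in calls.values() if c.status in ("homozygote", "heterozygote")]
    panel, flagged, threshold = apply_maf_filter(panel, len(resolved_calls) or 1, resolved_calls, maf_numerator)

    # translate sequences to names in the final calls
    seq2name = {e.seq: e.name for e in panel.entries}
    final: list[GenotypeCall] = []
    for ind in sorted(calls):
        c = calls[ind]
        a1 = seq2name.get(c.allele_1, c.allele_1) if c.allele_1 else None
        a2 = seq2name.get(c.allele_2, c.allele_2) if c.allele_2 else None
        if c.status in ("homozygote", "heterozygote") and (
            (c.allele_1 not in seq2name) or (c.allele_2 not in seq2name)
        ):
            # supported only by a frequency-filtered allele
            final.append(replace(c, allele_1=a1, allele_2=a2, status="unresolved", resolution_source="none"))
        else:
            final.append(replace(c, allele_1=a1, allele_2=a2))

    report = {
        "n_individuals": len(calls),
        "n_ambiguous_initial": n_ambiguous,
        "n_unresolved_final": sum(1 for c in final if c.status not in ("homozygote", "heterozygote")),
        "maf_threshold": threshold,
        "flagged_individuals": flagged,
        "n_alleles": len(panel.entries),
    }
    return final, panel, report
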