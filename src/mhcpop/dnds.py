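"""Synonymous / nonsynonymous substitution counting (pathway method) and dN/dS.

Per-codon synonymous site fractions and substitution counts follow the
classical pathway-counting method: each codon position contributes the
fraction of its three possible changes that are synonymous; codons differing
at several positions are averaged over all shortest substitution pathways,
excluding pathways passing through a stop codon.  dS and dN are
Jukes-Cantor-corrected proportions, and the panel summary averages dN and dS
over all sequence pairs before taking the ratio (the SNAP convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

from .seqstats import AlignedPanel

__all__ = [
    "SubstitutionCounts",
    "codon_sites",
    "codon_substitutions",
    "nei_gojobori",
    "panel_dnds",
    "cumulative_dnds_profile",
]

_BASES = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass
class SubstitutionCounts:
    syn_sites: float
    nonsyn_sites: float
    syn_subs: float
    nonsyn_subs: float
    ds: float
    dn: float

    @property
    def ratio(self) -> float:
        """dN/dS; NaN when dS is zero or undefined."""
        if not self.ds or math.isnan(self.ds) or math.isinf(self.ds):
            return float("nan")
        return self.dn / self.ds


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Position i contributes s_i = (# synonymous single-base changes at i) / 3;
    changes producing stop codons count as nonsynonymous.  The two fractions
    sum to 3 exactly.
    """
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if mutant not in _STOPS and _aa(mutant) == _aa(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons,
    averaged over all shortest pathways; pathways through a stop codon are
    excluded (if every pathway is blocked, all are used as a fallback)."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diffs):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if (cur not in _STOPS and nxt not in _STOPS) and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in pathways if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in pathways]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def _jc(p: float) -> float:
    """Jukes-Cantor correction of a substitution proportion."""
    if math.isnan(p):
        return float("nan")
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(codon_seq_a: str, codon_seq_b: str) -> SubstitutionCounts:
    """Pathway-method substitution counts between two in-frame sequences.

    Sequences must be equal length and a multiple of 3; codons containing a
    gap (or a stop codon in either sequence) are skipped.  Site totals are the
    average of the two sequences' potential sites.  Symmetric in its
    arguments.
    """
    if len(codon_seq_a) != len(codon_seq_b):
        raise ValueError("sequences must have equal length")
    if len(codon_seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    syn_sites = nonsyn_sites = 0.0
    sd = nd = 0.0
    for i in range(0, len(codon_seq_a), 3):
        ca = codon_seq_a[i : i + 3]
        cb = codon_seq_b[i : i + 3]
        if any(c not in _BASES for c in ca + cb):
            continue  # gapped or ambiguous codon skipped
        if ca in _STOPS or cb in _STOPS:
            continue
        sa = codon_sites(ca)
        sb = codon_sites(cb)
        syn_sites += (sa[0] + sb[0]) / 2.0
        nonsyn_sites += (sa[1] + sb[1]) / 2.0
        s, n = codon_substitutions(ca, cb)
        sd += s
        nd += n
    ps = sd / syn_sites if syn_sites else float("nan")
    pn = nd / nonsyn_sites if nonsyn_sites else float("nan")
    return SubstitutionCounts(
        syn_sites=syn_sites, nonsyn_sites=nonsyn_sites, syn_subs=sd, nonsyn_subs=nd,
        ds=_jc(ps), dn=_jc(pn),
    )


def panel_dnds(panel: AlignedPanel) -> dict:
    """Average substitution rates over all unordered sequence pairs of an
    in-frame panel; the summary ratio is mean(dN) / mean(dS), not the mean of
    per-pair ratios."""
    pairs = list(combinations(range(panel.n_rows), 2))
    if not pairs:
        raise ValueError("panel dN/dS requires at least two sequences")
    ds_vals, dn_vals, sd, nd = [], [], 0.0, 0.0
    for i, j in pairs:
        c = nei_gojobori(panel.seqs[i], panel.seqs[j])
        ds_vals.append(c.ds)
        dn_vals.append(c.dn)
        sd += c.syn_subs
        nd += c.nonsyn_subs
    mean_ds = float(np.nanmean(ds_vals))
    mean_dn = float(np.nanmean(dn_vals))
    return {
        "mean_ds": mean_ds,
        "mean_dn": mean_dn,
        "dn_ds": mean_dn / mean_ds if mean_ds else float("nan"),
        "mean_syn_subs": sd / len(pairs),
        "mean_nonsyn_subs": nd / len(pairs),
        "n_pairs": len(pairs),
    }


def cumulative_dnds_profile(panel: AlignedPanel) -> dict:
    """Running codon-indexed cumulative mean synonymous and nonsynonymous
    substitution counts, averaged over all sequence pairs (the codon-by-codon
    cumulative profile a SNAP-style analysis plots)."""
    L = panel.alignment_length
    if L % 3:
        raise ValueError("panel must be in frame (length a multiple of 3)")
    n_codons = L // 3
    pairs = list(combinations(range(panel.n_rows), 2))
    if not pairs:
        raise ValueError("profile requires at least two sequences")
    syn = np.zeros(n_codons)
    nonsyn = np.zeros(n_codons)
    for i, j in pairs:
        for c in range(n_codons):
            ca = panel.seqs[i][3 * c : 3 * c + 3]
            cb = panel.seqs[j][3 * c : 3 * c + 3]
            if any(x not in _BASES for x in ca + cb) or ca in _STOPS or cb in _STOPS:
                continue
            s, n = codon_substitutions(ca, cb)
            syn[c] += s
            nonsyn[c] += n
    syn /= len(pairs)
    nonsyn /= len(pairs)
    return {
        "codon": np.arange(1, n_codons + 1),
        "cum_syn": np.cumsum(syn),
        "cum_nonsyn": np.cumsum(nonsyn),
        "per_codon_syn": syn,
        "per_codon_nonsyn": nonsyn,
    }
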