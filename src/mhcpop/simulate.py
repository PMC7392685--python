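"""Synthetic two-locus amplicon data with the error structure of MiSeq MHC genotyping.

The generator emulates the study conditions of a fenced deer herd genotyped at
two MHC class II loci by deep amplicon sequencing: diploid genotypes at stated
allele frequencies with tunable departure from Hardy-Weinberg proportions and
tunable inter-locus association, per-individual read depths in the tens of
thousands, heterozygote allele balance centred near 58:42, homozygote noise
near 99:1, single-crossover PCR chimeras of an individual's two true alleles,
allele-specific amplification dropout, singleton error reads, and reads
shorter than the amplicon.  Every read record carries a provenance label so
downstream calling can be scored against truth.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AlleleSequence, PopulationSample, reverse_complement

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "ReadRecord",
    "simulate_allele_panel",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_pedigree",
    "inherit_genotypes",
    "corrupt_genotypes",
    "write_fastq",
    "reads_to_fastq_text",
]

_BASES = "ACGT"

# Default primers.  The reverse primer pair for the second locus is the
# published DOB amplicon primer pair; the first locus uses a fixed synthetic
# pair of comparable length (the classical-locus primers are not public).
DEFAULT_PRIMERS: dict[str, tuple[str, str]] = {
    # 29 + 28 bp, so the primered classical-locus amplicon is 250 + 57 = 307 bp
    "DRB": ("GATCCTCTCTCTGCAGCACATTTCTTGGA", "CACACTCACCTCGCCTCAGCACTGAAGT"),
    "DOB": ("AAAGCCCTCCTCTCCAATCC", "CCACCAAGGAGACCCCAAC"),
}


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed group of identical merged reads with a provenance label."""

    seq: str
    count: int
    provenance: str  # true-allele | error | chimera | short


@dataclass
class TruthTable:
    """Ground truth for every downstream stage."""

    genotypes: dict[str, dict[str, tuple[str, str]]]
    pedigree: pd.DataFrame  # columns: individual, sire, dam (empty string = unknown)
    reads: dict[tuple[str, str], list[ReadRecord]] = field(default_factory=dict)

    def provenance_counts(self, individual: str, locus: str) -> Counter:
        c: Counter = Counter()
        for r in self.reads.get((individual, locus), []):
            c[r.provenance] += r.count
        return c

    def total_reads(self, individual: str, locus: str) -> int:
        return sum(r.count for r in self.reads.get((individual, locus), []))


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults reflect the sequencing statistics the genotyper must survive:
    depth ~20k reads per individual per locus, 0.1% per-base error, 2% chimera
    rate, heterozygote balance Beta(8.4, 8.4) (median top-two share ~0.42,
    i.e. 58:42), no dropout unless requested.
    """

    seed: int = 0
    n_individuals: int = 200
    allele_panel_per_locus: dict[str, list[AlleleSequence]] = field(default_factory=dict)
    allele_frequencies: dict[str, np.ndarray] = field(default_factory=dict)
    inbreeding_f: float = 0.0
    ld_coefficient: float = 0.0  # standardized D' between the first alleles of the two loci
    depth_mean: float = 20_000.0
    depth_dispersion: float = 3.0  # negative-binomial size; var = mu + mu^2/size
    het_balance_alpha_beta: tuple[float, float] = (8.4, 8.4)
    error_rate_per_base: float = 0.001
    chimera_rate: float = 0.02
    dropout_alleles: dict[str, float] = field(default_factory=dict)  # name -> efficiency in (0,1]
    short_read_rate: float = 0.005
    singleton_noise_rate: float = 0.002
    primers: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_PRIMERS))
    orientation_flip_prob: float = 0.5  # fraction of read groups emitted reverse-complemented

    def validate(self) -> None:
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        for p in (
            self.error_rate_per_base,
            self.chimera_rate,
            self.short_read_rate,
            self.singleton_noise_rate,
            self.orientation_flip_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not -1.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [-1, 1]")
        if not -1.0 <= self.ld_coefficient <= 1.0:
            raise ValueError("ld_coefficient (standardized D') must lie in [-1, 1]")
        a, b = self.het_balance_alpha_beta
        if a <= 0 or b <= 0:
            raise ValueError("het balance Beta parameters must be positive")
        for name, m in self.dropout_alleles.items():
            if not 0.0 < m <= 1.0:
                raise ValueError(f"dropout multiplier for {name} must be in (0, 1]")
        for locus, freqs in self.allele_frequencies.items():
            freqs = np.asarray(freqs, dtype=float)
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies at {locus} sum to {freqs.sum()}, not 1")
            if (freqs < 0).any():
                raise ValueError(f"negative allele frequency at {locus}")
            panel = self.allele_panel_per_locus.get(locus)
            if panel is not None and len(panel) != len(freqs):
                raise ValueError(f"{locus}: {len(panel)} alleles but {len(freqs)} frequencies")

    @property
    def loci(self) -> list[str]:
        return list(self.allele_panel_per_locus)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A ready-to-run two-locus configuration with generated allele panels.

    Locus shapes follow the study template: a highly polymorphic 250 bp
    classical locus (19 alleles, 85 segregating sites) and a conserved 360 bp
    non-classical locus (11 alleles, 7 segregating sites, 270 bp exon).
    Allele frequencies are a geometric-ish decreasing profile normalised to 1.
    """
    drb = simulate_allele_panel(19, 250, 85, seed=seed * 7 + 1, name_prefix="Odvi-DRB*", start_serial=19)
    dob = [
        replace(a, exon=(45, 315))
        for a in simulate_allele_panel(11, 360, 7, seed=seed * 7 + 2, name_prefix="Odvi-DOB*", start_serial=1)
    ]

    def geom(n: int) -> np.ndarray:
        w = 0.82 ** np.arange(n)
        return w / w.sum()

    cfg = SimulationConfig(
        seed=seed,
        allele_panel_per_locus={"DRB": drb, "DOB": dob},
        allele_frequencies={"DRB": geom(19), "DOB": geom(11)},
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# allele panels


def simulate_allele_panel(
    n_alleles: int,
    length: int,
    n_variable_sites: int,
    seed: int,
    name_prefix: str = "SIM*",
    start_serial: int = 1,
) -> list[AlleleSequence]:
    """Generate ``n_alleles`` distinct sequences of ``length`` bp differing only at
    ``n_variable_sites`` chosen positions, with every chosen position actually
    polymorphic (so the panel's segregating-site count equals the request).
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if n_variable_sites > length:
        raise ValueError("n_variable_sites cannot exceed sequence length")
    capacity = 4**n_variable_sites if n_variable_sites < 32 else float("inf")
    if n_alleles > capacity:
        raise ValueError(
            f"cannot make {n_alleles} distinct alleles with only {n_variable_sites} variable sites"
        )
    if n_variable_sites > 0 and n_alleles < 2:
        raise ValueError("a single allele cannot segregate at any site")

    rng = np.random.default_rng(seed)
    backbone = rng.integers(0, 4, size=length)
    # exon-like backbone: recode frame-0 stop codons (TAA/TAG/TGA)
    stops = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}
    for c in range(length // 3):
        while tuple(backbone[3 * c : 3 * c + 3]) in stops:
            backbone[3 * c] = rng.integers(0, 3)  # anything but T at position 1
    var_sites = np.sort(rng.choice(length, size=n_variable_sites, replace=False))

    states = np.tile(backbone[var_sites], (n_alleles, 1)) if n_variable_sites else np.zeros((n_alleles, 0), int)
    if n_variable_sites:
        # sprinkle alternate states, then repair monomorphic columns / duplicate rows
        alt = rng.integers(0, 4, size=states.shape)
        mask = rng.random(states.shape) < 0.5
        states = np.where(mask, alt, states)
        for _ in range(10_000):
            fixed = True
            for j in range(n_variable_sites):
                if len(np.unique(states[:, j])) < 2:
                    i = int(rng.integers(n_alleles))
                    states[i, j] = (states[i, j] + int(rng.integers(1, 4))) % 4
                    fixed = False
            seen: dict[bytes, int] = {}
            for i in range(n_alleles):
                key = states[i].tobytes()
                if key in seen:
                    j = int(rng.integers(n_variable_sites))
                    states[i, j] = (states[i, j] + int(rng.integers(1, 4))) % 4
                    fixed = False
                else:
                    seen[key] = i
            if fixed:
                break
        else:  # pragma: no cover - bounded repair failed
            raise RuntimeError("could not construct a valid panel; try another seed")

    panel = []
    for i in range(n_alleles):
        arr = backbone.copy()
        if n_variable_sites:
            arr[var_sites] = states[i]
        seq = "".join(_BASES[b] for b in arr)
        panel.append(AlleleSequence(name=f"{name_prefix}{start_serial + i:02d}", seq=seq))
    return panel


# ---------------------------------------------------------------------------
# genotypes


def _genotype_matrix(freqs: np.ndarray, f: float) -> np.ndarray:
    """Unordered genotype probabilities with inbreeding coefficient ``f``:
    P(ii) = p_i^2 + f p_i (1 - p_i), P(ij) = 2 p_i p_j (1 - f)."""
    k = len(freqs)
    mat = np.zeros((k, k))
    for i in range(k):
        mat[i, i] = freqs[i] ** 2 + f * freqs[i] * (1 - freqs[i])
        for j in range(i + 1, k):
            mat[i, j] = 2 * freqs[i] * freqs[j] * (1 - f)
    if (mat < -1e-12).any():
        raise ValueError(f"inbreeding_f={f} infeasible for the given allele frequencies")
    mat = np.clip(mat, 0.0, None)
    return mat / mat.sum()


def _haplotype_freqs(p: np.ndarray, q: np.ndarray, d_prime: float) -> np.ndarray:
    """Two-locus haplotype frequencies with standardized LD ``d_prime`` placed on
    the (first allele, first allele) pair; all other combinations scaled to
    preserve the marginals."""
    p0, q0 = p[0], q[0]
    if d_prime >= 0:
        dmax = min(p0 * (1 - q0), (1 - p0) * q0)
    else:
        dmax = min(p0 * q0, (1 - p0) * (1 - q0))
    d = d_prime * dmax
    h = np.outer(p, q)
    h00 = p0 * q0 + d
    h[0, 0] = h00
    if len(q) > 1 and q0 < 1:
        h[0, 1:] = (p0 - h00) * q[1:] / (1 - q0)
    if len(p) > 1 and p0 < 1:
        h[1:, 0] = (q0 - h00) * p[1:] / (1 - p0)
        if len(q) > 1 and q0 < 1:
            rest = 1 - p0 - q0 + h00
            h[1:, 1:] = np.outer(p[1:], q[1:]) * rest / ((1 - p0) * (1 - q0))
    if (h < -1e-12).any():
        raise ValueError(f"ld_coefficient={d_prime} infeasible for the given allele frequencies")
    h = np.clip(h, 0.0, None)
    return h / h.sum()


def simulate_genotypes(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PopulationSample, TruthTable]:
    """Draw diploid genotypes for ``config.n_individuals`` unrelated individuals.

    Per-locus genotype frequencies follow the inbreeding parameterization; with
    ``ld_coefficient == 0`` loci are drawn independently, otherwise gametes are
    drawn from coupled haplotype frequencies (requires ``inbreeding_f >= 0``,
    applied as an autozygosity mixture).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    loci = config.loci
    names = {loc: [a.name for a in config.allele_panel_per_locus[loc]] for loc in loci}
    individuals = [f"ind{i:04d}" for i in range(config.n_individuals)]
    genotypes: dict[str, dict[str, tuple[str, str]]] = {i: {} for i in individuals}

    if config.ld_coefficient != 0.0 and len(loci) == 2:
        if config.inbreeding_f < 0:
            raise ValueError("negative inbreeding_f unsupported together with ld_coefficient != 0")
        la, lb = loci
        p = np.asarray(config.allele_frequencies[la], dtype=float)
        q = np.asarray(config.allele_frequencies[lb], dtype=float)
        h = _haplotype_freqs(p, q, config.ld_coefficient)
        flat = h.ravel()
        kb = len(q)
        for ind in individuals:
            h1 = int(rng.choice(len(flat), p=flat))
            if config.inbreeding_f > 0 and rng.random() < config.inbreeding_f:
                h2 = h1
            else:
                h2 = int(rng.choice(len(flat), p=flat))
            a1, b1 = divmod(h1, kb)
            a2, b2 = divmod(h2, kb)
            genotypes[ind][la] = tuple(sorted((names[la][a1], names[la][a2])))
            genotypes[ind][lb] = tuple(sorted((names[lb][b1], names[lb][b2])))
    else:
        for loc in loci:
            freqs = np.asarray(config.allele_frequencies[loc], dtype=float)
            gmat = _genotype_matrix(freqs, config.inbreeding_f)
            k = len(freqs)
            iu = [(i, j) for i in range(k) for j in range(i, k)]
            probs = np.array([gmat[i, j] for i, j in iu])
            draws = rng.choice(len(iu), size=len(individuals), p=probs)
            for ind, g in zip(individuals, draws):
                i, j = iu[g]
                genotypes[ind][loc] = tuple(sorted((names[loc][i], names[loc][j])))

    sample = PopulationSample(loci=loci, individuals=individuals, genotypes=genotypes)
    pedigree = pd.DataFrame({"individual": individuals, "sire": "", "dam": ""})
    return sample, TruthTable(genotypes=genotypes, pedigree=pedigree)


# ---------------------------------------------------------------------------
# pedigrees


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    seed: int,
    config: Optional[SimulationConfig] = None,
    offspring_per_generation: Optional[int] = None,
) -> tuple[pd.DataFrame, PopulationSample, TruthTable]:
    """Build a random pedigree and Mendelian-inherited genotypes.

    Founders (labelled cohort "founding") draw genotypes from the config's
    frequency model; every non-founder inherits exactly one allele from each
    recorded parent.  The last generation is labelled cohort "final".
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if config is None:
        config = default_config(seed=seed)
    rng = np.random.default_rng(seed)
    founder_cfg = replace(config, n_individuals=n_founders)
    founder_sample, _ = simulate_genotypes(founder_cfg, rng=rng)

    rows = [{"individual": i, "sire": "", "dam": "", "generation": 0} for i in founder_sample.individuals]
    genotypes = {i: dict(founder_sample.genotypes[i]) for i in founder_sample.individuals}
    # arbitrary sex split: even index = sire pool, odd = dam pool
    sires = founder_sample.individuals[0::2]
    dams = founder_sample.individuals[1::2]
    n_off = offspring_per_generation if offspring_per_generation is not None else n_founders
    counter = n_founders
    for gen in range(1, n_generations + 1):
        new_sires, new_dams = [], []
        for _ in range(n_off):
            ind = f"ind{counter:04d}"
            counter += 1
            sire = sires[int(rng.integers(len(sires)))]
            dam = dams[int(rng.integers(len(dams)))]
            rows.append({"individual": ind, "sire": sire, "dam": dam, "generation": gen})
            genotypes[ind] = {}
            for loc in config.loci:
                gs = genotypes[sire][loc]
                gd = genotypes[dam][loc]
                a = gs[int(rng.integers(2))]
                b = gd[int(rng.integers(2))]
                genotypes[ind][loc] = tuple(sorted((a, b)))
            (new_sires if rng.random() < 0.5 else new_dams).append(ind)
        sires = sires + new_sires
        dams = dams + new_dams

    ped = pd.DataFrame(rows)
    individuals = list(ped["individual"])
    cohorts = {
        r["individual"]: ("founding" if r["generation"] == 0 else ("final" if r["generation"] == n_generations else ""))
        for r in rows
    }
    sample = PopulationSample(loci=config.loci, individuals=individuals, genotypes=genotypes, cohorts=cohorts)
    truth = TruthTable(genotypes=genotypes, pedigree=ped[["individual", "sire", "dam"]].copy())
    return ped, sample, truth


def inherit_genotypes(
    pedigree: pd.DataFrame,
    founder_genotypes: dict[str, dict[str, tuple[str, str]]],
    seed: int,
) -> dict[str, dict[str, tuple[str, str]]]:
    """Propagate genotypes down an arbitrary pedigree (founders given explicitly)."""
    rng = np.random.default_rng(seed)
    genotypes = {i: dict(g) for i, g in founder_genotypes.items()}
    remaining = [r for _, r in pedigree.iterrows() if r["individual"] not in genotypes]
    guard = 0
    while remaining:
        progressed = []
        for r in remaining:
            sire, dam = r["sire"], r["dam"]
            if sire in genotypes and dam in genotypes:
                g = {}
                for loc in genotypes[sire]:
                    a = genotypes[sire][loc][int(rng.integers(2))]
                    b = genotypes[dam][loc][int(rng.integers(2))]
                    g[loc] = tuple(sorted((a, b)))
                genotypes[r["individual"]] = g
                progressed.append(r["individual"])
        remaining = [r for r in remaining if r["individual"] not in genotypes]
        guard += 1
        if not progressed and remaining:
            raise ValueError("pedigree contains unresolvable (cyclic or parentless) individuals")
        if guard > len(pedigree) + 1:  # pragma: no cover
            raise RuntimeError("pedigree propagation did not converge")
    return genotypes


def corrupt_genotypes(
    sample: PopulationSample,
    fraction: float,
    seed: int,
    locus: Optional[str] = None,
    eligible: Optional[Sequence[str]] = None,
) -> tuple[PopulationSample, list[str]]:
    """Randomly replace both alleles of a fraction of individuals with alleles
    drawn from the observed panel — a stand-in for genotyping error when
    checking pedigree-consistency rates.  ``eligible`` restricts corruption to
    a subset (e.g. terminal offspring, so one error does not cascade through
    the descendants)."""
    rng = np.random.default_rng(seed)
    loci = [locus] if locus else sample.loci
    pool = {loc: sorted({a for i in sample.individuals for a in sample.genotypes[i][loc]}) for loc in loci}
    corrupted = []
    genotypes = {i: dict(g) for i, g in sample.genotypes.items()}
    eligible_set = set(eligible) if eligible is not None else None
    for ind in sample.individuals:
        if eligible_set is not None and ind not in eligible_set:
            continue
        if rng.random() < fraction:
            corrupted.append(ind)
            for loc in loci:
                alleles = pool[loc]
                a = alleles[int(rng.integers(len(alleles)))]
                b = alleles[int(rng.integers(len(alleles)))]
                genotypes[ind][loc] = tuple(sorted((a, b)))
    out = PopulationSample(
        loci=sample.loci, individuals=sample.individuals, genotypes=genotypes, cohorts=dict(sample.cohorts)
    )
    return out, corrupted


# ---------------------------------------------------------------------------
# reads


def _mutate(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_errors, replace=False)
    chars = list(seq)
    for p in pos:
        old = chars[p]
        choices = [b for b in _BASES if b != old]
        chars[p] = choices[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    sample: PopulationSample,
    config: SimulationConfig,
    truth: Optional[TruthTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[tuple[str, str], list[ReadRecord]], TruthTable]:
    """Generate per-individual merged amplicon read sets as collapsed records.

    A read is the full merged amplicon: forward primer + allele + revcomp of
    the reverse primer.  Read depth is negative-binomial; heterozygote top-two
    balance is Beta-distributed then scaled by any dropout efficiency
    multipliers; chimeras are single-crossover recombinants of the
    individual's two allele sequences; per-base errors are uniform; singleton
    noise reads carry several extra substitutions; short reads are truncated
    below the merged-length floor.  Records are returned collapsed by
    sequence within provenance class.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    seqs = {
        loc: {a.name: a.seq for a in config.allele_panel_per_locus[loc]} for loc in config.loci
    }
    reads: dict[tuple[str, str], list[ReadRecord]] = {}
    if truth is None:
        truth = TruthTable(
            genotypes=sample.genotypes,
            pedigree=pd.DataFrame({"individual": sample.individuals, "sire": "", "dam": ""}),
        )

    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    alpha, beta = config.het_balance_alpha_beta

    for ind in sample.individuals:
        for loc in sample.loci:
            fwd, rev = config.primers.get(loc, ("", ""))
            rev_rc = reverse_complement(rev)
            a1, a2 = sample.genotypes[ind][loc]
            s1, s2 = seqs[loc][a1], seqs[loc][a2]
            amp1 = fwd + s1 + rev_rc
            amp2 = fwd + s2 + rev_rc
            het = a1 != a2

            depth = int(rng.negative_binomial(config.depth_dispersion, p_nb))
            depth = max(depth, 20)

            chim_rate = config.chimera_rate if het else 0.0
            n_chim = rng.binomial(depth, chim_rate)
            n_short = rng.binomial(depth - n_chim, config.short_read_rate)
            n_single = rng.binomial(depth - n_chim - n_short, config.singleton_noise_rate)
            n_true = depth - n_chim - n_short - n_single

            if het:
                bal = rng.beta(alpha, beta)
                w1 = bal * config.dropout_alleles.get(a1, 1.0)
                w2 = (1 - bal) * config.dropout_alleles.get(a2, 1.0)
                n1 = rng.binomial(n_true, w1 / (w1 + w2))
            else:
                n1 = n_true
            n2 = n_true - n1

            records: list[ReadRecord] = []

            def emit_true(amp: str, n: int) -> None:
                if n == 0:
                    return
                errs = rng.binomial(len(amp), config.error_rate_per_base, size=n)
                clean = int((errs == 0).sum())
                if clean:
                    records.append(ReadRecord(amp, clean, "true-allele"))
                mutated = Counter(
                    _mutate(amp, int(k), rng) for k in errs[errs > 0]
                )
                for sq, c in sorted(mutated.items()):
                    records.append(ReadRecord(sq, c, "error"))

            emit_true(amp1, n1)
            if het:
                emit_true(amp2, n2)

            if n_chim:
                L = min(len(s1), len(s2))
                xs = rng.integers(1, L, size=n_chim)
                order = rng.random(n_chim) < 0.5
                chis = Counter()
                for x, first in zip(xs, order):
                    body = (s1[:x] + s2[x:]) if first else (s2[:x] + s1[x:])
                    chis[fwd + body + rev_rc] += 1
                for sq, c in sorted(chis.items()):
                    if sq != amp1 and sq != amp2:
                        records.append(ReadRecord(sq, c, "chimera"))
                    else:  # crossover in an identical stretch reproduces a parent
                        records.append(ReadRecord(sq, c, "true-allele"))

            for _ in range(n_short):
                cut = int(rng.integers(40, max(41, len(amp1) - 20)))
                records.append(ReadRecord(amp1[:cut], 1, "short"))

            for _ in range(n_single):
                src = amp2 if (het and rng.random() < 0.5) else amp1
                records.append(ReadRecord(_mutate(src, 4, rng), 1, "error"))

            if config.orientation_flip_prob > 0:
                flipped = []
                for r in records:
                    if rng.random() < config.orientation_flip_prob:
                        flipped.append(ReadRecord(reverse_complement(r.seq), r.count, r.provenance))
                    else:
                        flipped.append(r)
                records = flipped

            reads[(ind, loc)] = records
            truth.reads[(ind, loc)] = records
    return reads, truth


# ---------------------------------------------------------------------------
# FASTQ / truth output


def reads_to_fastq_text(records: Iterable[ReadRecord], individual: str, locus: str) -> str:
    """Expand collapsed records into standard 4-line FASTQ with constant Q37."""
    buf = io.StringIO()
    idx = 0
    for r in records:
        for _ in range(r.count):
            idx += 1
            buf.write(f"@{individual}:{locus}:{idx} {r.provenance}\n{r.seq}\n+\n{'F' * len(r.seq)}\n")
    return buf.getvalue()


def write_fastq(reads: dict[tuple[str, str], list[ReadRecord]], out_dir) -> list[str]:
    """One FASTQ per (individual, locus); returns the written paths."""
    import os

    paths = []
    os.makedirs(out_dir, exist_ok=True)
    for (ind, loc), records in sorted(reads.items()):
        path = os.path.join(out_dir, f"{ind}_{loc}.fastq")
        with open(path, "w") as fh:
            fh.write(reads_to_fastq_text(records, ind, loc))
        paths.append(path)
    return paths


def truth_to_frame(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for (ind, loc), records in sorted(truth.reads.items()):
        for r in records:
            rows.append({"individual": ind, "locus": loc, "sequence": r.seq, "count": r.count, "provenance": r.provenance})
    return pd.DataFrame(rows)
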