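"""Benchmark experiments on synthetic data.

Each function regenerates data under the study conditions and measures one
property of the pipeline: genotype recovery and chimera handling under default
noise, behaviour under allele-specific amplification dropout, and the type-I
error / power of the exact Hardy-Weinberg and genotypic-LD tests.  These are
the computations the analysis drivers and the acceptance script report.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .caller import detect_chimera, genotype_population
from .core import PopulationSample, reverse_complement
from .popgen import GenotypeArray, McmcSettings, hwe_probability_test, ld_genotypic_test
from .read_filter import filter_merged_reads
from .simulate import (
    DEFAULT_PRIMERS,
    SimulationConfig,
    simulate_allele_panel,
    simulate_pedigree,
    simulate_reads,
)

__all__ = [
    "single_locus_config",
    "recovery_experiment",
    "dropout_experiment",
    "hwe_type1_calibration",
    "ld_type1_calibration",
    "ld_power_experiment",
]


def single_locus_config(seed: int, locus: str = "DRB", **overrides) -> SimulationConfig:
    """One classical-locus study template: 19 alleles, 250 bp, 85 variable sites,
    geometric-ish decreasing allele frequencies."""
    panel = simulate_allele_panel(19, 250, 85, seed=seed * 11 + 3, name_prefix=f"Odvi-{locus}*", start_serial=19)
    w = 0.82 ** np.arange(19)
    cfg = SimulationConfig(
        seed=seed,
        allele_panel_per_locus={locus: panel},
        allele_frequencies={locus: w / w.sum()},
        primers={locus: DEFAULT_PRIMERS["DRB"]},
        **overrides,
    )
    cfg.validate()
    return cfg


def _run_calling(
    cfg: SimulationConfig,
    locus: str,
    n_founders: int,
    n_offspring: int,
    seed: int,
    sanger_founders: bool = False,
):
    """Simulate a pedigreed population, sequence it, filter and genotype it.

    With ``sanger_founders`` the founders' true genotypes are supplied as
    independently determined external genotypes (the Sanger-sequenced
    pre-fence individuals of the study design); otherwise founders carry only
    an external validation flag.
    """
    ped, sample, truth = simulate_pedigree(
        n_founders, 2, seed=seed, config=cfg, offspring_per_generation=n_offspring
    )
    reads, truth = simulate_reads(sample, cfg, truth=truth)
    fwd, rev = cfg.primers[locus]
    tables = {
        ind: filter_merged_reads(reads[(ind, locus)], fwd, rev, min_len=290, individual_id=ind, locus=locus)
        for ind in sample.individuals
    }
    founders = set(ped.loc[(ped["sire"] == "") & (ped["dam"] == ""), "individual"])
    external_genotypes = None
    if sanger_founders:
        allele_seq = {a.name: a.seq for a in cfg.allele_panel_per_locus[locus]}
        external_genotypes = {
            f: tuple(sorted(allele_seq[a] for a in truth.genotypes[f][locus])) for f in founders
        }
    calls, panel, report = genotype_population(
        list(tables.values()), pedigree=ped, external=founders, locus=locus,
        external_genotypes=external_genotypes,
    )
    return ped, sample, truth, reads, tables, calls, panel, report


def recovery_experiment(seed: int, n_individuals: int = 200, depth_mean: float = 20_000.0) -> dict:
    """Genotype recovery under default noise (0.1% per-base error, 2% chimeras,
    no dropout) and the fate of every injected chimera that survives filtering.
    """
    locus = "DRB"
    n_founders = n_individuals // 2
    n_off = (n_individuals - n_founders) // 2
    cfg = single_locus_config(seed, locus, n_individuals=n_individuals, depth_mean=depth_mean)
    ped, sample, truth, reads, tables, calls, panel, report = _run_calling(
        cfg, locus, n_founders, n_off, seed
    )

    allele_seq = {a.name: a.seq for a in cfg.allele_panel_per_locus[locus]}
    name2seq = {e.name: e.seq for e in panel.entries}
    n_total = n_correct = 0
    het_ratios, hom_ratios = [], []
    for c in calls:
        truth_pair = tuple(sorted(allele_seq[a] for a in truth.genotypes[c.individual_id][locus]))
        n_total += 1
        if c.status in ("homozygote", "heterozygote"):
            got = tuple(sorted(name2seq.get(a, "") for a in (c.allele_1, c.allele_2)))
            if got == truth_pair:
                n_correct += 1
        if truth_pair[0] != truth_pair[1] and c.status == "heterozygote" and c.resolution_source == "ratio":
            het_ratios.append(c.top2_ratio)
        if truth_pair[0] == truth_pair[1] and c.status == "homozygote" and c.top2_ratio > 0:
            hom_ratios.append(c.top2_ratio)

    # every chimera sequence surviving the read filters must rank below both
    # true alleles and be recognisable as a single-crossover recombinant
    fwd, rev = cfg.primers[locus]
    n_chim = n_chim_below = n_chim_flagged = 0
    for ind in sample.individuals:
        a1, a2 = (allele_seq[a] for a in truth.genotypes[ind][locus])
        chim_inserts = set()
        for r in truth.reads[(ind, locus)]:
            if r.provenance != "chimera":
                continue
            s = r.seq if r.seq.startswith(fwd) else reverse_complement(r.seq)
            chim_inserts.add(s[len(fwd): len(s) - len(rev)])
        table = tables[ind]
        ranked = table.sequences
        for row_idx, s in enumerate(ranked):
            if s not in chim_inserts:
                continue
            n_chim += 1
            idx_true = [ranked.index(x) for x in (a1, a2) if x in ranked]
            if idx_true and row_idx > max(idx_true):
                n_chim_below += 1
            if s != a1 and s != a2 and detect_chimera(s, a1, a2).is_chimera:
                n_chim_flagged += 1
    return {
        "n_individuals": n_total,
        "recovery_fraction": n_correct / n_total,
        "n_ambiguous_initial": report["n_ambiguous_initial"],
        "n_surviving_chimera_variants": n_chim,
        "chimera_ranked_below_fraction": (n_chim_below / n_chim) if n_chim else 1.0,
        "chimera_flagged_fraction": (n_chim_flagged / n_chim) if n_chim else 1.0,
        "median_het_ratio": float(np.median(het_ratios)) if het_ratios else float("nan"),
        "median_hom_ratio": float(np.median(hom_ratios)) if hom_ratios else float("nan"),
        "n_alleles_called": report["n_alleles"],
    }


def dropout_experiment(
    seed: int, multiplier: float = 0.25, n_individuals: int = 200, depth_mean: float = 5_000.0
) -> dict:
    """Allele-specific dropout: the affected heterozygotes' top-two ratio drops
    into the ambiguous 10-35% zone and must be recovered through the pedigree
    (or the external validation of founders)."""
    locus = "DRB"
    cfg = single_locus_config(seed, locus, n_individuals=n_individuals, depth_mean=depth_mean)
    dropout_name = cfg.allele_panel_per_locus[locus][1].name  # a common allele
    cfg = replace(cfg, dropout_alleles={dropout_name: multiplier})
    n_founders = n_individuals // 2
    n_off = (n_individuals - n_founders) // 2
    ped, sample, truth, reads, tables, calls, panel, report = _run_calling(
        cfg, locus, n_founders, n_off, seed, sanger_founders=True
    )
    allele_seq = {a.name: a.seq for a in cfg.allele_panel_per_locus[locus]}
    name2seq = {e.name: e.seq for e in panel.entries}
    calls_by_id = {c.individual_id: c for c in calls}

    affected = [
        ind
        for ind in sample.individuals
        if dropout_name in truth.genotypes[ind][locus]
        and truth.genotypes[ind][locus][0] != truth.genotypes[ind][locus][1]
    ]
    ratios = [calls_by_id[i].top2_ratio for i in affected]
    # recovery is scored on the heterozygotes the ratio rule leaves ambiguous
    ambiguous_band = [i for i in affected if 0.10 <= calls_by_id[i].top2_ratio < 0.35]
    recovered = 0
    for ind in ambiguous_band:
        c = calls_by_id[ind]
        truth_pair = tuple(sorted(allele_seq[a] for a in truth.genotypes[ind][locus]))
        if c.status in ("homozygote", "heterozygote"):
            got = tuple(sorted(name2seq.get(a, "") for a in (c.allele_1, c.allele_2)))
            recovered += got == truth_pair
    return {
        "n_affected_heterozygotes": len(affected),
        "n_in_ambiguous_band": len(ambiguous_band),
        "median_affected_ratio": float(np.median(ratios)) if ratios else float("nan"),
        "recovered_fraction": recovered / len(ambiguous_band) if ambiguous_band else float("nan"),
        "expected_share": multiplier / (1 + multiplier),
    }


def _hwe_genotype_probs(freqs: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    k = len(freqs)
    pairs, probs = [], []
    for i in range(k):
        for j in range(i, k):
            pairs.append((i, j))
            probs.append(freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j])
    return pairs, np.asarray(probs)


def hwe_type1_calibration(
    seed: int,
    n_datasets: int = 1000,
    n_individuals: int = 100,
    freqs: tuple[float, ...] = (0.5, 0.3, 0.2),
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the exact HWE probability test on data simulated under
    Hardy-Weinberg proportions (exhaustive enumeration for every dataset)."""
    rng = np.random.default_rng(seed)
    pairs, probs = _hwe_genotype_probs(np.asarray(freqs))
    k = len(freqs)
    rejections = 0
    used = 0
    for _ in range(n_datasets):
        draws = rng.multinomial(n_individuals, probs)
        counts = np.zeros((k, k), dtype=int)
        for (i, j), c in zip(pairs, draws):
            counts[i, j] += c
        counts = counts + np.triu(counts, 1).T
        arr = GenotypeArray("L", [f"a{i}" for i in range(k)], counts)
        res = hwe_probability_test(arr)
        if np.isnan(res.p):
            continue
        used += 1
        rejections += res.p <= alpha
    rate = rejections / used
    se = float(np.sqrt(alpha * (1 - alpha) / used))
    return {"rate": rate, "se": se, "n_datasets": used, "alpha": alpha}


def _sample_from_codes(codes_a, codes_b, pairs, alleles_a, alleles_b) -> PopulationSample:
    inds = [f"i{j}" for j in range(len(codes_a))]
    genos = {}
    for ind, ca, cb in zip(inds, codes_a, codes_b):
        i, j = pairs[ca]
        u, v = pairs[cb]
        genos[ind] = {
            "A": tuple(sorted((alleles_a[i], alleles_a[j]))),
            "B": tuple(sorted((alleles_b[u], alleles_b[v]))),
        }
    return PopulationSample(loci=["A", "B"], individuals=inds, genotypes=genos)


def ld_type1_calibration(
    seed: int,
    n_datasets: int = 1000,
    n_individuals: int = 100,
    freqs: tuple[float, ...] = (0.5, 0.3, 0.2),
    n_permutations: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the genotypic LD test on two independently drawn loci."""
    rng = np.random.default_rng(seed)
    pairs, probs = _hwe_genotype_probs(np.asarray(freqs))
    aa = [f"a{i}" for i in range(len(freqs))]
    bb = [f"b{i}" for i in range(len(freqs))]
    rejections = used = 0
    for rep in range(n_datasets):
        ca = rng.choice(len(pairs), size=n_individuals, p=probs)
        cb = rng.choice(len(pairs), size=n_individuals, p=probs)
        sample = _sample_from_codes(ca, cb, pairs, aa, bb)
        settings = McmcSettings(
            dememorization=1, batches=1, iterations_per_batch=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        res = ld_genotypic_test(sample, "A", "B", settings)
        if np.isnan(res.p):
            continue
        used += 1
        rejections += res.p <= alpha
    rate = rejections / used
    se = float(np.sqrt(alpha * (1 - alpha) / used))
    return {"rate": rate, "se": se, "n_datasets": used, "alpha": alpha}


def ld_power_experiment(
    seed: int,
    n_individuals: int = 100,
    freqs: tuple[float, ...] = (0.5, 0.3, 0.2),
    n_permutations: int = 1999,
) -> dict:
    """Complete two-locus association: every locus-A genotype is mirrored at
    locus B, so the independence test must reject decisively."""
    rng = np.random.default_rng(seed)
    pairs, probs = _hwe_genotype_probs(np.asarray(freqs))
    aa = [f"a{i}" for i in range(len(freqs))]
    bb = [f"b{i}" for i in range(len(freqs))]
    ca = rng.choice(len(pairs), size=n_individuals, p=probs)
    sample = _sample_from_codes(ca, ca, pairs, aa, bb)
    settings = McmcSettings(
        dememorization=1, batches=1, iterations_per_batch=n_permutations, seed=seed + 1
    )
    res = ld_genotypic_test(sample, "A", "B", settings)
    return {"p": res.p, "g_statistic": res.statistic, "n_permutations": n_permutations}
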