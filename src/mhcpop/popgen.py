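"""Genotype-level inference: frequencies, exact HWE tests, genotypic LD, Ne.

The Hardy-Weinberg tests condition on the observed allele counts (the Levene
distribution of genotype arrays, equivalently random pairing of allele
copies).  The probability test sums the probability of all arrays no more
probable than the observed one; the score tests direct power at heterozygote
excess or deficit using the total heterozygote count as the score statistic.
Small array spaces are enumerated exhaustively; larger ones use the
Guo-Thompson Markov chain with GenePop-style settings (dememorization,
batches, iterations per batch) and a batch-means standard error.

The two-locus genotypic independence (LD) test computes the log-likelihood
-ratio G statistic on the genotype contingency table and builds the null by
permuting one locus' single-locus genotypes among individuals, making no
phase assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import PopulationSample

__all__ = [
    "GenotypeArray",
    "McmcSettings",
    "TestResult",
    "frequencies",
    "hwe_probability_test",
    "hwe_score_tests",
    "ld_genotypic_test",
    "effective_population_size",
]


@dataclass
class McmcSettings:
    dememorization: int = 1000
    batches: int = 100
    iterations_per_batch: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dememorization, self.batches, self.iterations_per_batch) <= 0:
            raise ValueError("all MCMC settings must be positive")


@dataclass
class TestResult:
    p: float
    se: float = 0.0
    method: str = "enumeration"
    statistic: float = float("nan")
    n_arrays: int = 0

    @property
    def applicable(self) -> bool:
        return not math.isnan(self.p)


NOT_APPLICABLE = TestResult(p=float("nan"), se=float("nan"), method="not-applicable")


@dataclass
class GenotypeArray:
    """Symmetric genotype-count matrix n_ij over allele names at one locus."""

    locus: str
    alleles: list[str]
    counts: np.ndarray  # (k, k) symmetric, upper triangle authoritative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.alleles)
        if self.counts.shape != (k, k):
            raise ValueError("counts matrix shape mismatch")
        if (self.counts < 0).any() or not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be a non-negative symmetric matrix")

    @classmethod
    def from_sample(cls, sample: PopulationSample, locus: str) -> "GenotypeArray":
        alleles = sorted({a for i in sample.individuals for a in sample.genotypes[i][locus]})
        idx = {a: i for i, a in enumerate(alleles)}
        k = len(alleles)
        counts = np.zeros((k, k), dtype=int)
        for ind in sample.individuals:
            a, b = sample.genotypes[ind][locus]
            i, j = idx[a], idx[b]
            counts[min(i, j), max(i, j)] += 1
        counts = counts + np.triu(counts, 1).T
        return cls(locus=locus, alleles=alleles, counts=counts)

    @property
    def n(self) -> int:
        return int(np.triu(self.counts).sum())

    def allele_counts(self) -> np.ndarray:
        """Allele copy counts: row sums plus the diagonal once more."""
        return np.triu(self.counts).sum(axis=0) + np.triu(self.counts).sum(axis=1)

    def het_count(self) -> int:
        return int(np.triu(self.counts, 1).sum())


# ---------------------------------------------------------------------------
# frequencies


def frequencies(sample: PopulationSample, by_cohort: bool = False) -> dict:
    """Allele and unordered-genotype frequency tables per locus (and cohort)."""

    def tables(sub: PopulationSample) -> dict:
        out = {}
        for locus in sub.loci:
            if not sub.individuals:
                out[locus] = {"alleles": pd.Series(dtype=float), "genotypes": pd.Series(dtype=float)}
                continue
            arr = GenotypeArray.from_sample(sub, locus)
            ac = arr.allele_counts()
            allele_freq = pd.Series(ac / (2 * arr.n), index=arr.alleles).sort_values(ascending=False)
            geno = {}
            for i, a in enumerate(arr.alleles):
                for j in range(i, len(arr.alleles)):
                    c = arr.counts[i, j]
                    if c:
                        geno[f"{a}/{arr.alleles[j]}"] = c / arr.n
            out[locus] = {
                "alleles": allele_freq,
                "genotypes": pd.Series(geno).sort_values(ascending=False),
            }
        return out

    if not by_cohort:
        return tables(sample)
    labels = sorted({c for c in sample.cohorts.values() if c})
    return {label: tables(sample.cohort(label)) for label in labels}


# ---------------------------------------------------------------------------
# the Levene conditional distribution


def _log_prob_terms(counts: np.ndarray) -> float:
    """- sum_{i<=j} log n_ij! + (#het copies) log 2 for a genotype array."""
    upper = counts[np.triu_indices_from(counts)]
    het = int(np.triu(counts, 1).sum())
    return float(het * math.log(2.0) - gammaln(upper + 1.0).sum())


def _log_const(n: int, allele_counts: np.ndarray) -> float:
    return float(gammaln(n + 1) + gammaln(allele_counts + 1.0).sum() - gammaln(2 * n + 1))


def _enumerate_arrays(allele_counts: np.ndarray, cap: Optional[int] = 100_000):
    """Yield all symmetric genotype-count matrices with the given allele-copy
    marginals.  Raises OverflowError when more than ``cap`` arrays exist."""
    k = len(allele_counts)
    counts = np.zeros((k, k), dtype=int)
    produced = 0

    def rec(i: int, j: int, remaining: np.ndarray):
        nonlocal produced
        if i == k:
            yield counts.copy()
            produced += 1
            if cap is not None and produced > cap:
                raise OverflowError("array space larger than enumeration cap")
            return
        if j == k:
            # close row i: diagonal takes the remaining copies of allele i
            if remaining[i] >= 0 and remaining[i] % 2 == 0:
                counts[i, i] = remaining[i] // 2
                rem2 = remaining.copy()
                rem2[i] = 0
                yield from rec(i + 1, i + 2, rem2)
                counts[i, i] = 0
            return
        mx = min(remaining[i], remaining[j])
        for c in range(int(mx) + 1):
            counts[i, j] = counts[j, i] = c
            rem2 = remaining.copy()
            rem2[i] -= c
            rem2[j] -= c
            yield from rec(i, j + 1, rem2)
        counts[i, j] = counts[j, i] = 0

    yield from rec(0, 1, np.asarray(allele_counts, dtype=int).copy())


def _enumerate_stats_k3(allele_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exhaustive enumeration for the three-allele case: grid over
    the three heterozygote counts; homozygote counts follow from the marginals."""
    a1, a2, a3 = (int(x) for x in allele_counts)
    g12, g13, g23 = np.meshgrid(
        np.arange(min(a1, a2) + 1), np.arange(min(a1, a3) + 1), np.arange(min(a2, a3) + 1),
        indexing="ij",
    )
    r1 = a1 - g12 - g13
    r2 = a2 - g12 - g23
    r3 = a3 - g13 - g23
    valid = (r1 >= 0) & (r2 >= 0) & (r3 >= 0) & (r1 % 2 == 0) & (r2 % 2 == 0) & (r3 % 2 == 0)
    g12, g13, g23 = g12[valid], g13[valid], g23[valid]
    h11, h22, h33 = r1[valid] // 2, r2[valid] // 2, r3[valid] // 2
    hets = g12 + g13 + g23
    logp = hets * math.log(2.0) - (
        gammaln(g12 + 1.0) + gammaln(g13 + 1.0) + gammaln(g23 + 1.0)
        + gammaln(h11 + 1.0) + gammaln(h22 + 1.0) + gammaln(h33 + 1.0)
    )
    n = (a1 + a2 + a3) // 2
    return logp + _log_const(n, np.asarray(allele_counts)), hets


def _enumerate_stats(allele_counts: np.ndarray, cap: int = 100_000) -> tuple[np.ndarray, np.ndarray]:
    """(log-probabilities, heterozygote counts) over the full array space."""
    allele_counts = np.asarray(allele_counts)
    if len(allele_counts) == 3:
        return _enumerate_stats_k3(allele_counts)
    logps, hets = [], []
    for arr in _enumerate_arrays(allele_counts, cap=cap):
        logps.append(_log_prob_terms(arr))
        hets.append(int(np.triu(arr, 1).sum()))
    n = int(allele_counts.sum()) // 2
    const = _log_const(n, allele_counts)
    return np.asarray(logps) + const, np.asarray(hets)


_REL_TOL = 1e-12


def _guo_thompson_chain(
    arr: GenotypeArray,
    settings: McmcSettings,
    indicator,
) -> TestResult:
    """Metropolis chain on genotype arrays with allele counts fixed.

    Proposal: pick two individuals and swap one allele between them (the
    classic switch move); acceptance uses the Levene probability ratio.
    ``indicator(counts, log_terms, het_count)`` marks states contributing to
    the p-value.
    The p estimate and its standard error come from batch means.
    """
    rng = np.random.default_rng(settings.seed)
    counts = arr.counts.copy()
    k = len(arr.alleles)

    # individuals as a flat list of genotype index pairs
    genos: list[list[int]] = []
    for i in range(k):
        for j in range(i, k):
            genos.extend([[i, j]] * int(counts[i, j]))
    n = len(genos)
    if n < 2:
        return TestResult(p=1.0, se=0.0, method="mcmc", n_arrays=0)

    log_terms = _log_prob_terms(counts)
    het_count = int(np.triu(counts, 1).sum())
    log2 = math.log(2.0)
    lgamma = math.lgamma

    # random streams drawn in blocks; on the labelled-individual state space
    # the stationary weight 2^H is exactly cancelled by the proposal asymmetry
    # (a homozygote offers its allele at two positions), so every valid swap
    # is accepted and dlog only maintains the running array log-probability
    # for the probability-test indicator
    def run_block(n_steps: int, collect: bool) -> int:
        nonlocal log_terms, het_count
        idx = rng.integers(0, n, size=(n_steps, 2))
        sides = rng.integers(0, 2, size=(n_steps, 2))
        hits = 0
        for t in range(n_steps):
            i1, i2 = idx[t]
            if i1 != i2:
                g1, g2 = genos[i1], genos[i2]
                s1, s2 = sides[t]
                a, b = g1[s1], g2[s2]
                if a != b:
                    new1 = sorted((g1[1 - s1], b))
                    new2 = sorted((g2[1 - s2], a))
                    delta = {}
                    for key, d in ((tuple(sorted(g1)), -1), (tuple(sorted(g2)), -1),
                                   ((new1[0], new1[1]), 1), ((new2[0], new2[1]), 1)):
                        delta[key] = delta.get(key, 0) + d
                    dlog = 0.0
                    for (x, y), d in delta.items():
                        if d == 0:
                            continue
                        c_old = counts[x, y]
                        dlog += lgamma(c_old + 1) - lgamma(c_old + d + 1)
                        if x != y:
                            dlog += d * log2
                            het_count += d
                        counts[x, y] += d
                        if x != y:
                            counts[y, x] += d
                    genos[i1] = new1
                    genos[i2] = new2
                    log_terms += dlog
            if collect and indicator(counts, log_terms, het_count):
                hits += 1
        return hits

    run_block(settings.dememorization, collect=False)
    batch_means = []
    for _ in range(settings.batches):
        hits = run_block(settings.iterations_per_batch, collect=True)
        batch_means.append(hits / settings.iterations_per_batch)
    bm = np.asarray(batch_means)
    p = float(bm.mean())
    se = float(bm.std(ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else float("nan")
    return TestResult(p=p, se=se, method="mcmc", n_arrays=settings.batches * settings.iterations_per_batch)


def _array_space_bound(allele_counts: np.ndarray) -> float:
    """Cheap upper bound on the number of genotype arrays (product over allele
    pairs of the heterozygote-count range)."""
    a = sorted(int(x) for x in allele_counts)
    bound = 1.0
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            bound *= min(a[i], a[j]) + 1
            if bound > 1e12:
                return bound
    return bound


def _dispatch(arr: GenotypeArray, mode: str, cap: int = 100_000) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Try exhaustive enumeration; None means fall back to the chain."""
    if mode == "mcmc":
        return None
    ac = arr.allele_counts()
    ac = ac[ac > 0]
    if mode == "auto":
        limit = 5e6 if len(ac) == 3 else 1e6
        if _array_space_bound(ac) > limit:
            return None
    try:
        return _enumerate_stats(ac, cap=cap)
    except OverflowError:
        if mode == "enumerate":
            raise
        return None


def hwe_probability_test(
    arr: GenotypeArray,
    settings: Optional[McmcSettings] = None,
    mode: str = "auto",
) -> TestResult:
    """Exact conditional HWE probability test.

    p is the total Levene probability of genotype arrays no more probable than
    the observed one (ties included with a relative tolerance so the observed
    array itself always counts).  Monomorphic loci are not applicable.
    """
    settings = settings or McmcSettings()
    if len(arr.alleles) < 2 or (arr.allele_counts() > 0).sum() < 2:
        return NOT_APPLICABLE
    obs_terms = _log_prob_terms(arr.counts)
    enum = _dispatch(arr, mode)
    if enum is not None:
        logps, _ = enum
        obs = obs_terms + _log_const(arr.n, arr.allele_counts())
        thresh = obs + _REL_TOL * abs(obs)
        p = float(np.exp(logps[logps <= thresh]).sum())
        return TestResult(p=min(p, 1.0), se=0.0, method="enumeration",
                          statistic=obs, n_arrays=len(logps))

    def indicator(counts: np.ndarray, log_terms: float, het: int) -> bool:
        return log_terms <= obs_terms + _REL_TOL * abs(obs_terms)

    res = _guo_thompson_chain(arr, settings, indicator)
    res.statistic = obs_terms
    return res


def hwe_score_tests(
    arr: GenotypeArray,
    settings: Optional[McmcSettings] = None,
    direction: str = "deficit",
    mode: str = "auto",
) -> TestResult:
    """One-sided heterozygote excess / deficit score test under the same
    conditional null: p = P(het count >= observed) for excess, <= for deficit.
    p_excess + p_deficit >= 1 on any array (ties counted in both tails)."""
    if direction not in ("excess", "deficit"):
        raise ValueError("direction must be 'excess' or 'deficit'")
    settings = settings or McmcSettings()
    if len(arr.alleles) < 2 or (arr.allele_counts() > 0).sum() < 2:
        return NOT_APPLICABLE
    h_obs = arr.het_count()
    enum = _dispatch(arr, mode)
    if enum is not None:
        logps, hets = enum
        sel = hets >= h_obs if direction == "excess" else hets <= h_obs
        p = float(np.exp(logps[sel]).sum())
        return TestResult(p=min(p, 1.0), se=0.0, method="enumeration",
                          statistic=h_obs, n_arrays=len(logps))

    if direction == "excess":
        indicator = lambda counts, lt, het: het >= h_obs
    else:
        indicator = lambda counts, lt, het: het <= h_obs
    res = _guo_thompson_chain(arr, settings, indicator)
    res.statistic = h_obs
    return res


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G on a contingency table (zero cells skipped)."""
    total = table.sum()
    if total == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_genotypic_test(
    sample: PopulationSample,
    locus_a: str,
    locus_b: str,
    settings: Optional[McmcSettings] = None,
) -> TestResult:
    """Two-locus genotypic independence test.

    G is computed on the locus-A genotype x locus-B genotype table over
    individuals carrying resolved calls at both loci; the null distribution is
    built by permuting locus-B genotypes among individuals (batches x
    iterations permutations after ``dememorization`` warm-up draws are
    discarded).  p uses the add-one permutation estimator, with a batch-means
    standard error.
    """
    settings = settings or McmcSettings()
    ga = [tuple(sample.genotypes[i][locus_a]) for i in sample.individuals]
    gb = [tuple(sample.genotypes[i][locus_b]) for i in sample.individuals]
    ca = {g: i for i, g in enumerate(sorted(set(ga)))}
    cb = {g: i for i, g in enumerate(sorted(set(gb)))}
    if len(ca) < 2 or len(cb) < 2:
        return NOT_APPLICABLE
    xa = np.array([ca[g] for g in ga])
    xb = np.array([cb[g] for g in gb])
    ka, kb = len(ca), len(cb)

    def table(bvec: np.ndarray) -> np.ndarray:
        return np.bincount(xa * kb + bvec, minlength=ka * kb).reshape(ka, kb)

    g_obs = _g_statistic(table(xb))
    rng = np.random.default_rng(settings.seed)
    for _ in range(settings.dememorization // max(settings.iterations_per_batch, 1)):
        rng.permutation(xb)  # warm-up draws, discarded
    hits = 0
    total = 0
    batch_means = []
    for _ in range(settings.batches):
        bh = 0
        for _ in range(settings.iterations_per_batch):
            perm = rng.permutation(xb)
            if _g_statistic(table(perm)) >= g_obs - 1e-12:
                bh += 1
        batch_means.append(bh / settings.iterations_per_batch)
        hits += bh
        total += settings.iterations_per_batch
    p = (1 + hits) / (1 + total)
    bm = np.asarray(batch_means)
    se = float(bm.std(ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else float("nan")
    return TestResult(p=float(p), se=se, method="permutation", statistic=g_obs, n_arrays=total)


# ---------------------------------------------------------------------------


def effective_population_size(n_m: int, n_f: int) -> float:
    """Breeding-sex-ratio effective size Ne = 4 Nm Nf / (Nm + Nf)."""
    if n_m <= 0 or n_f <= 0:
        raise ValueError("both sexes must have at least one breeder")
    return 4.0 * n_m * n_f / (n_m + n_f)
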