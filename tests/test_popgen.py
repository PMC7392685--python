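"""Exact HWE tests vs a random-pairing oracle, LD permutation test, frequencies, Ne."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from mhcpop.core import PopulationSample
from mhcpop.popgen import (
    GenotypeArray,
    McmcSettings,
    effective_population_size,
    frequencies,
    hwe_probability_test,
    hwe_score_tests,
    ld_genotypic_test,
)


# ---------------------------------------------------------------------------
# oracle: the Levene conditional null is random pairing of the 2n allele copies


def _pairings(copies):
    """Enumerate all perfect matchings of a list of allele labels."""
    if not copies:
        yield []
        return
    first, rest = copies[0], copies[1:]
    for i in range(len(rest)):
        pair = tuple(sorted((first, rest[i])))
        for tail in _pairings(rest[:i] + rest[i + 1 :]):
            yield [pair] + tail


def _oracle_distribution(allele_counts):
    """Exact array distribution: map each matching to its genotype array."""
    copies = []
    for idx, c in enumerate(allele_counts):
        copies.extend([idx] * c)
    arrays = {}
    total = 0
    for matching in _pairings(copies):
        key = tuple(sorted(matching))
        arrays[key] = arrays.get(key, 0) + 1
        total += 1
    return {k: Fraction(v, total) for k, v in arrays.items()}, total


def _array_key(counts):
    k = counts.shape[0]
    out = []
    for i in range(k):
        for j in range(i, k):
            out.extend([(i, j)] * int(counts[i, j]))
    return tuple(sorted(out))


def _oracle_pvalues(arr: GenotypeArray):
    dist, _ = _oracle_distribution(list(arr.allele_counts()))
    obs_key = _array_key(arr.counts)
    p_obs = dist[obs_key]
    prob_p = sum(p for p in dist.values() if p <= p_obs)
    h = lambda key: sum(1 for (i, j) in key if i != j)
    h_obs = h(obs_key)
    p_exc = sum(p for key, p in dist.items() if h(key) >= h_obs)
    p_def = sum(p for key, p in dist.items() if h(key) <= h_obs)
    return float(prob_p), float(p_exc), float(p_def)


def _random_array(rng, n, k):
    genos = rng.integers(0, k, size=(n, 2))
    counts = np.zeros((k, k), dtype=int)
    for a, b in genos:
        i, j = min(a, b), max(a, b)
        counts[i, j] += 1
    counts = counts + np.triu(counts, 1).T
    alleles = [chr(65 + i) for i in range(k)]
    arr = GenotypeArray("L", alleles, counts)
    if (arr.allele_counts() > 0).sum() < 2:
        return None
    return arr


class TestHwExactTests:
    def test_two_individual_textbook_case(self):
        # allele counts (2,2), observed {AA, aa}: arrays {Aa=2} w.p. 2/3 and
        # {AA,aa} w.p. 1/3, so the probability-test p is exactly 1/3
        arr = GenotypeArray("L", ["A", "a"], np.array([[1, 0], [0, 1]]))
        assert hwe_probability_test(arr).p == pytest.approx(1 / 3, abs=1e-12)

    def test_degenerate_single_heterozygote(self):
        arr = GenotypeArray("L", ["A", "a"], np.array([[0, 1], [1, 0]]))
        assert hwe_probability_test(arr).p == pytest.approx(1.0)

    def test_monomorphic_not_applicable(self):
        arr = GenotypeArray("L", ["A"], np.array([[5]]))
        assert math.isnan(hwe_probability_test(arr).p)
        assert math.isnan(hwe_score_tests(arr, direction="excess").p)

    @pytest.mark.parametrize("seed", range(8))
    def test_enumeration_matches_random_pairing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = _random_array(rng, int(rng.integers(2, 5)), int(rng.integers(2, 4)))
        if arr is None:
            pytest.skip("monomorphic draw")
        exp_prob, exp_exc, exp_def = _oracle_pvalues(arr)
        assert hwe_probability_test(arr, mode="enumerate").p == pytest.approx(exp_prob, abs=1e-10)
        assert hwe_score_tests(arr, direction="excess", mode="enumerate").p == pytest.approx(exp_exc, abs=1e-10)
        assert hwe_score_tests(arr, direction="deficit", mode="enumerate").p == pytest.approx(exp_def, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_mcmc_agrees_with_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        arr = _random_array(rng, 12, 3)
        if arr is None:
            pytest.skip("monomorphic draw")
        settings = McmcSettings(dememorization=2000, batches=40, iterations_per_batch=500, seed=seed)
        e = hwe_probability_test(arr, mode="enumerate")
        m = hwe_probability_test(arr, settings, mode="mcmc")
        assert abs(e.p - m.p) < 3 * m.se + 1e-9

    def test_identical_seed_reproduces_mcmc_p(self):
        rng = np.random.default_rng(7)
        arr = _random_array(rng, 15, 3)
        s = McmcSettings(dememorization=500, batches=10, iterations_per_batch=200, seed=42)
        assert hwe_probability_test(arr, s, mode="mcmc").p == hwe_probability_test(arr, s, mode="mcmc").p

    def test_tails_overlap(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            arr = _random_array(rng, 10, 3)
            if arr is None:
                continue
            pe = hwe_score_tests(arr, direction="excess").p
            pd = hwe_score_tests(arr, direction="deficit").p
            assert pe + pd >= 1.0 - 1e-9

    def test_direction_of_extreme_arrays(self):
        all_het = GenotypeArray("L", ["A", "a"], np.array([[0, 10], [10, 0]]))
        assert hwe_score_tests(all_het, direction="excess").p <= hwe_score_tests(all_het, direction="deficit").p
        all_hom = GenotypeArray("L", ["A", "a"], np.array([[5, 0], [0, 5]]))
        assert hwe_score_tests(all_hom, direction="deficit").p <= hwe_score_tests(all_hom, direction="excess").p


def _two_locus_sample(ga, gb):
    n = len(ga)
    inds = [f"i{j}" for j in range(n)]
    return PopulationSample(
        loci=["A", "B"],
        individuals=inds,
        genotypes={
            ind: {"A": tuple(sorted(a)), "B": tuple(sorted(b))} for ind, a, b in zip(inds, ga, gb)
        },
    )


class TestLdGenotypicTest:
    def test_monomorphic_locus_not_applicable(self):
        ga = [("x", "y")] * 10
        gb = [("u", "u")] * 10
        res = ld_genotypic_test(_two_locus_sample(ga, gb), "A", "B")
        assert math.isnan(res.p)

    def test_perfect_association_rejected(self):
        rng = np.random.default_rng(11)
        alleles = ["a1", "a2", "a3"]
        ga = [tuple(rng.choice(alleles, 2)) for _ in range(100)]
        gb = [tuple(g.replace("a", "b") for g in pair) for pair in ga]
        settings = McmcSettings(dememorization=1, batches=15, iterations_per_batch=100, seed=5)
        res = ld_genotypic_test(_two_locus_sample(ga, gb), "A", "B", settings)
        assert res.p < 0.001

    def test_g_invariant_to_allele_relabelling(self):
        rng = np.random.default_rng(13)
        alleles = ["a1", "a2"]
        ga = [tuple(rng.choice(alleles, 2)) for _ in range(60)]
        gb = [tuple(rng.choice(["b1", "b2"], 2)) for _ in range(60)]
        s = McmcSettings(dememorization=1, batches=2, iterations_per_batch=50, seed=1)
        g1 = ld_genotypic_test(_two_locus_sample(ga, gb), "A", "B", s).statistic
        swap = {"a1": "a2", "a2": "a1"}
        ga2 = [tuple(swap[g] for g in pair) for pair in ga]
        g2 = ld_genotypic_test(_two_locus_sample(ga2, gb), "A", "B", s).statistic
        assert g1 == pytest.approx(g2)

    def test_identical_seed_reproduces_p(self):
        rng = np.random.default_rng(17)
        ga = [tuple(rng.choice(["a1", "a2"], 2)) for _ in range(40)]
        gb = [tuple(rng.choice(["b1", "b2"], 2)) for _ in range(40)]
        s = McmcSettings(dememorization=1, batches=5, iterations_per_batch=100, seed=9)
        sample = _two_locus_sample(ga, gb)
        assert ld_genotypic_test(sample, "A", "B", s).p == ld_genotypic_test(sample, "A", "B", s).p


class TestFrequencies:
    def test_all_homozygous_single_allele(self):
        sample = _two_locus_sample([("A", "A")] * 10, [("u", "u")] * 10)
        out = frequencies(sample)
        assert out["A"]["alleles"]["A"] == pytest.approx(1.0)

    def test_mixed_pair(self):
        sample = _two_locus_sample([("A", "A"), ("A", "B")], [("u", "u")] * 2)
        out = frequencies(sample)
        assert out["A"]["alleles"]["A"] == pytest.approx(0.75)
        assert out["A"]["alleles"]["B"] == pytest.approx(0.25)

    def test_genotype_frequencies_normalised(self):
        rng = np.random.default_rng(19)
        ga = [tuple(rng.choice(["A", "B", "C"], 2)) for _ in range(30)]
        sample = _two_locus_sample(ga, [("u", "u")] * 30)
        out = frequencies(sample)
        assert out["A"]["genotypes"].sum() == pytest.approx(1.0)


class TestEffectivePopulationSize:
    def test_equal_sexes(self):
        assert effective_population_size(50, 50) == pytest.approx(100.0)

    def test_skewed_sexes_matches_harmonic_formula(self):
        assert effective_population_size(46, 25) == pytest.approx(64.79, abs=0.01)

    def test_bounded_by_census(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m, f = int(rng.integers(1, 500)), int(rng.integers(1, 500))
            assert effective_population_size(m, f) <= m + f

    def test_zero_breeders_rejected(self):
        with pytest.raises(ValueError):
            effective_population_size(0, 10)
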