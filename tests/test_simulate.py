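"""Generator behaviour: panels, genotype models, read error structure, pedigrees."""

import numpy as np
import pytest

from mhcpop.caller import mendelian_consistency
from mhcpop.core import reverse_complement
from mhcpop.seqstats import AlignedPanel, segregating_sites
from mhcpop.simulate import (
    SimulationConfig,
    corrupt_genotypes,
    default_config,
    inherit_genotypes,
    reads_to_fastq_text,
    simulate_allele_panel,
    simulate_genotypes,
    simulate_pedigree,
    simulate_reads,
)

import pandas as pd


def _noiseless(cfg: SimulationConfig) -> SimulationConfig:
    from dataclasses import replace

    return replace(
        cfg, error_rate_per_base=0.0, chimera_rate=0.0, short_read_rate=0.0,
        singleton_noise_rate=0.0, orientation_flip_prob=0.0,
    )


class TestAllelePanel:
    @pytest.mark.parametrize(
        "n_alleles,length,n_sites",
        [(1, 250, 0), (2, 10, 3), (19, 250, 85), (5, 40, 12)],
    )
    def test_segregating_sites_hit_request_exactly(self, n_alleles, length, n_sites):
        panel = simulate_allele_panel(n_alleles, length, n_sites, seed=3)
        assert len(panel) == n_alleles
        assert len({a.seq for a in panel}) == n_alleles
        assert all(len(a.seq) == length for a in panel)
        aligned = AlignedPanel("x", [a.name for a in panel], [a.seq for a in panel])
        S, _ = segregating_sites(aligned)
        assert S == n_sites

    def test_two_alleles_three_sites_hamming_bounds(self):
        a, b = simulate_allele_panel(2, 10, 3, seed=5)
        d = sum(x != y for x, y in zip(a.seq, b.seq))
        assert 1 <= d <= 3

    def test_impossible_distinctness_raises(self):
        with pytest.raises(ValueError):
            simulate_allele_panel(2, 10, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_allele_panel(17, 30, 2, seed=1)  # 4^2 = 16 < 17

    def test_deterministic_under_seed(self):
        p1 = simulate_allele_panel(6, 80, 9, seed=42)
        p2 = simulate_allele_panel(6, 80, 9, seed=42)
        assert [a.seq for a in p1] == [a.seq for a in p2]


class TestGenotypeModel:
    def _config(self, freqs, f=0.0, n=10_000, ld=0.0, two_loci=False):
        panel = simulate_allele_panel(len(freqs), 30, len(freqs), seed=9, name_prefix="A*")
        panels = {"L1": panel}
        fr = {"L1": np.asarray(freqs, dtype=float)}
        if two_loci:
            panels["L2"] = simulate_allele_panel(len(freqs), 30, len(freqs), seed=10, name_prefix="B*")
            fr["L2"] = np.asarray(freqs, dtype=float)
        return SimulationConfig(
            seed=21, n_individuals=n, allele_panel_per_locus=panels,
            allele_frequencies=fr, inbreeding_f=f, ld_coefficient=ld,
        )

    def test_hwe_heterozygote_fraction(self):
        sample, _ = simulate_genotypes(self._config([0.5, 0.5]))
        het = sum(
            sample.genotypes[i]["L1"][0] != sample.genotypes[i]["L1"][1] for i in sample.individuals
        )
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(het / 10_000 - 0.5) < 3 * se

    def test_complete_inbreeding_has_no_heterozygotes(self):
        sample, _ = simulate_genotypes(self._config([0.5, 0.5], f=1.0, n=2000))
        assert all(
            sample.genotypes[i]["L1"][0] == sample.genotypes[i]["L1"][1] for i in sample.individuals
        )

    def test_homozygote_fraction_at_skewed_frequencies(self):
        sample, _ = simulate_genotypes(self._config([0.7, 0.3]))
        names = [a.name for a in simulate_allele_panel(2, 30, 2, seed=9, name_prefix="A*")]
        hom1 = sum(sample.genotypes[i]["L1"] == (names[0], names[0]) for i in sample.individuals)
        se = np.sqrt(0.49 * 0.51 / 10_000)
        assert abs(hom1 / 10_000 - 0.49) < 3 * se

    def test_infeasible_inbreeding_raises(self):
        with pytest.raises(ValueError):
            simulate_genotypes(self._config([0.9, 0.1], f=-0.5, n=10))

    def test_ld_coefficient_bounds_checked(self):
        with pytest.raises(ValueError):
            simulate_genotypes(self._config([0.5, 0.5], ld=1.5, n=10, two_loci=True))

    def test_independent_loci_at_zero_ld(self):
        sample, _ = simulate_genotypes(self._config([0.5, 0.5], n=4000, two_loci=True))
        # correlation between first-allele dosages should vanish
        d1 = np.array([
            sum(a.endswith("01") for a in sample.genotypes[i]["L1"]) for i in sample.individuals
        ])
        d2 = np.array([
            sum(a.endswith("01") for a in sample.genotypes[i]["L2"]) for i in sample.individuals
        ])
        r = np.corrcoef(d1, d2)[0, 1]
        assert abs(r) < 3 / np.sqrt(4000)


class TestReads:
    def test_noiseless_homozygote_single_sequence(self, two_allele_config):
        from dataclasses import replace

        cfg = _noiseless(replace(two_allele_config, n_individuals=5, inbreeding_f=1.0))
        sample, truth = simulate_genotypes(cfg)
        reads, truth = simulate_reads(sample, cfg, truth=truth)
        for (ind, loc), records in reads.items():
            assert len({r.seq for r in records}) == 1
            assert all(r.provenance == "true-allele" for r in records)

    def test_chimera_fraction_matches_rate(self, two_allele_config):
        from dataclasses import replace

        cfg = replace(
            _noiseless(two_allele_config), chimera_rate=0.05, depth_mean=10_000.0,
            depth_dispersion=1e6, n_individuals=4, inbreeding_f=-1.0,  # all heterozygotes
        )
        sample, truth = simulate_genotypes(cfg)
        assert all(g[0] != g[1] for i in sample.individuals for g in [sample.genotypes[i]["L"]])
        reads, truth = simulate_reads(sample, cfg, truth=truth)
        counts = [truth.provenance_counts(i, "L") for i in sample.individuals]
        frac = sum(c["chimera"] for c in counts) / sum(sum(c.values()) for c in counts)
        n = sum(sum(c.values()) for c in counts)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_dropout_share_follows_ratio_algebra(self, two_allele_config):
        from dataclasses import replace

        dropout_name = two_allele_config.allele_panel_per_locus["L"][1].name
        cfg = replace(
            _noiseless(two_allele_config),
            dropout_alleles={dropout_name: 0.25},
            het_balance_alpha_beta=(5000.0, 5000.0),  # essentially symmetric balance
            depth_mean=20_000.0, depth_dispersion=1e6, n_individuals=30, inbreeding_f=-1.0,
        )
        sample, truth = simulate_genotypes(cfg)
        reads, _ = simulate_reads(sample, cfg, truth=truth)
        shares = []
        for (ind, loc), records in reads.items():
            by_count = sorted(records, key=lambda r: -r.count)[:2]
            b = [r for r in by_count if dropout_name in _origin(r, cfg)]
            total = sum(r.count for r in by_count)
            drop = sum(r.count for r in b)
            shares.append(drop / total)
        assert abs(np.median(shares) - 0.2) < 0.02

    def test_provenance_counts_conserve_depth(self, two_allele_config):
        from dataclasses import replace

        cfg = replace(two_allele_config, n_individuals=10)
        sample, truth = simulate_genotypes(cfg)
        reads, truth = simulate_reads(sample, cfg, truth=truth)
        for ind in sample.individuals:
            assert sum(truth.provenance_counts(ind, "L").values()) == truth.total_reads(ind, "L")

    def test_chimera_reads_reconstructable_from_parents(self, two_allele_config):
        from dataclasses import replace

        cfg = replace(_noiseless(two_allele_config), chimera_rate=0.05, n_individuals=6, inbreeding_f=-1.0)
        sample, truth = simulate_genotypes(cfg)
        reads, truth = simulate_reads(sample, cfg, truth=truth)
        seqs = {a.name: a.seq for a in cfg.allele_panel_per_locus["L"]}
        fwd, rev = cfg.primers["L"]
        rc = reverse_complement(rev)
        for ind in sample.individuals:
            a1, a2 = sample.genotypes[ind]["L"]
            amp1, amp2 = fwd + seqs[a1] + rc, fwd + seqs[a2] + rc
            for r in reads[(ind, "L")]:
                if r.provenance != "chimera":
                    continue
                ok = any(
                    r.seq == amp1[:k] + amp2[k:] or r.seq == amp2[:k] + amp1[k:]
                    for k in range(1, len(amp1))
                )
                assert ok

    def test_byte_identical_under_seed(self, two_allele_config):
        from dataclasses import replace

        cfg = replace(two_allele_config, n_individuals=6)
        out = []
        for _ in range(2):
            sample, truth = simulate_genotypes(cfg)
            reads, _ = simulate_reads(sample, cfg, truth=truth)
            text = "".join(
                reads_to_fastq_text(reads[k], *k) for k in sorted(reads)
            )
            out.append(text)
        assert out[0] == out[1]


def _origin(record, cfg):
    """Names of alleles whose amplicon matches a read record (orientation-aware)."""
    fwd, rev = cfg.primers["L"]
    rc = reverse_complement(rev)
    hits = []
    for a in cfg.allele_panel_per_locus["L"]:
        amp = fwd + a.seq + rc
        if record.seq in (amp, reverse_complement(amp)):
            hits.append(a.name)
    return hits


class TestPedigree:
    def test_forced_inheritance_ab(self):
        ped = pd.DataFrame(
            {
                "individual": ["f1", "f2", "o1", "o2", "o3"],
                "sire": ["", "", "f1", "f1", "f1"],
                "dam": ["", "", "f2", "f2", "f2"],
            }
        )
        founders = {"f1": {"L": ("A", "A")}, "f2": {"L": ("B", "B")}}
        geno = inherit_genotypes(ped, founders, seed=1)
        for o in ("o1", "o2", "o3"):
            assert geno[o]["L"] == ("A", "B")

    def test_noiseless_pedigree_fully_consistent(self):
        cfg = default_config(seed=2, n_individuals=30)
        ped, sample, truth = simulate_pedigree(20, 2, seed=2, config=cfg)
        flags, frac = mendelian_consistency(sample, ped)
        assert frac == 1.0

    def test_corruption_rate_reflected_in_consistency(self):
        cfg = default_config(seed=3)
        ped, sample, truth = simulate_pedigree(40, 2, seed=3, config=cfg, offspring_per_generation=120)
        # corrupt terminal offspring only, so each error affects exactly one trio
        parents = set(ped["sire"]) | set(ped["dam"])
        terminal = [i for i in sample.individuals if i not in parents and i not in set(ped.loc[ped["generation"] == 0, "individual"])]
        corrupted, hit = corrupt_genotypes(sample, 0.05, seed=4, eligible=terminal)
        flags, frac = mendelian_consistency(corrupted, ped)
        sub = [flags[i] for i in terminal if i in flags]
        frac_t = sum(sub) / len(sub)
        se = np.sqrt(0.95 * 0.05 / len(sub))
        # corrupted genotypes can still be consistent by chance, so the
        # observed fraction sits at or slightly above 1 - corruption rate
        assert 0.95 - 3 * se < frac_t <= 1.0

    def test_cyclic_pedigree_detected(self):
        ped = pd.DataFrame(
            {"individual": ["a", "b"], "sire": ["b", "a"], "dam": ["", ""]}
        )
        sample, _ = simulate_genotypes(default_config(seed=1, n_individuals=2))
        sample.genotypes = {"a": {"DRB": ("x", "x"), "DOB": ("y", "y")},
                            "b": {"DRB": ("x", "x"), "DOB": ("y", "y")}}
        sample.individuals = ["a", "b"]
        with pytest.raises(ValueError, match="cyclic"):
            mendelian_consistency(sample, ped)
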