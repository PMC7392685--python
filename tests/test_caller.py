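"""Ratio-threshold calling, chimera detection, MAF filter, nomenclature, pedigree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcpop.caller import (
    AllelePanel,
    PanelEntry,
    Thresholds,
    apply_maf_filter,
    assign_nomenclature,
    classify_individual,
    detect_chimera,
    genotype_population,
    mendelian_consistency,
)
from mhcpop.core import PopulationSample
from mhcpop.read_filter import RankedVariantTable, filter_merged_reads
from mhcpop.simulate import default_config, simulate_pedigree, simulate_reads


def table(counts, individual="ind", locus="L"):
    rows = [("SEQ%03d" % i + "ACGT" * 10, c) for i, c in enumerate(counts)]
    return RankedVariantTable(individual_id=individual, locus=locus, rows=rows)


class TestClassification:
    @pytest.mark.parametrize(
        "counts,status,ratio",
        [
            ((9900, 100), "homozygote", 0.01),       # the typical 99:1 homozygote
            ((580, 420), "heterozygote", 0.42),      # the typical 58:42 heterozygote
            ((800, 200), "ambiguous", 0.20),         # inside the 10-35% grey zone
            ((650, 350), "heterozygote", 0.35),      # 65:35 boundary is heterozygote
            ((900, 100), "ambiguous", 0.10),         # 90:10 boundary is not homozygote
            ((5000,), "homozygote", 0.0),            # single variant
        ],
    )
    def test_ratio_bands(self, counts, status, ratio):
        call = classify_individual(table(counts))
        assert call.status == status
        assert call.top2_ratio == pytest.approx(ratio)
        if status == "homozygote":
            assert call.allele_1 == call.allele_2

    def test_empty_table_is_unresolved(self):
        call = classify_individual(RankedVariantTable(individual_id="x"))
        assert call.status == "unresolved"
        assert call.resolution_source == "none"

    @given(st.integers(2, 10_000), st.integers(1, 10_000), st.integers(2, 50))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c1, c2, scale):
        c1, c2 = max(c1, c2), min(c1, c2)
        a = classify_individual(table((c1, c2)))
        b = classify_individual(table((c1 * scale, c2 * scale)))
        assert a.status == b.status
        assert a.top2_ratio == pytest.approx(b.top2_ratio)


class TestChimeraDetection:
    def test_constructed_single_crossover(self):
        hit = detect_chimera("ACGTTGCA", "ACGTACGT", "TGCATGCA")
        assert hit.is_chimera
        assert hit.interval == (4, 5)

    def test_foreign_base_rejected(self):
        # candidate has a base present in neither parent at site 0
        hit = detect_chimera("CCGTACGA", "ACGTACGT", "TCGTACGA")
        assert not hit.is_chimera

    def test_candidate_equal_to_parent_rejected(self):
        with pytest.raises(ValueError):
            detect_chimera("ACGTACGT", "ACGTACGT", "TGCATGCA")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_chimera("ACGT", "ACGTA", "TGCAT")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_symmetric_and_detects_all_crossovers(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), 30))
        b = "".join(rng.choice(list(bases), 30))
        k = int(rng.integers(1, 30))
        cand = a[:k] + b[k:]
        if cand in (a, b):
            return
        assert detect_chimera(cand, a, b).is_chimera
        assert detect_chimera(cand, b, a).is_chimera  # symmetric in (a, b)


class TestMafFilter:
    def _panel(self, freqs, validated=None):
        validated = validated or [False] * len(freqs)
        entries = [
            PanelEntry(name=f"X*{i:02d}", seq="ACGT" * 5 + "ACGT"[i % 4] * (i + 1), validated=v,
                       population_frequency=f)
            for i, (f, v) in enumerate(zip(freqs, validated))
        ]
        return AllelePanel(locus="X", entries=entries)

    @pytest.mark.parametrize("n,expected_pct", [(375, 0.67), (380, 0.66)])
    def test_threshold_matches_five_copy_rule(self, n, expected_pct):
        panel = self._panel([0.9, 0.1])
        _, _, threshold = apply_maf_filter(panel, n)
        assert threshold == pytest.approx(5 / (2 * n))
        assert round(100 * threshold, 2) == expected_pct

    def test_single_occurrence_unvalidated_removed(self):
        panel = self._panel([1 - 1 / 750, 1 / 750])
        filtered, _, _ = apply_maf_filter(panel, 375)
        assert len(filtered.entries) == 1

    def test_validated_allele_retained_below_threshold(self):
        panel = self._panel([1 - 1 / 750, 1 / 750], validated=[False, True])
        filtered, _, _ = apply_maf_filter(panel, 375)
        assert len(filtered.entries) == 2

    def test_idempotent(self):
        panel = self._panel([0.5, 0.494, 0.004, 0.002], validated=[False, False, True, False])
        once, _, _ = apply_maf_filter(panel, 375)
        twice, _, _ = apply_maf_filter(once, 375)
        assert [e.name for e in once.entries] == [e.name for e in twice.entries]


class TestNomenclature:
    def _known(self, n, prefix="Odvi-DRB*"):
        return AllelePanel(
            locus="DRB",
            entries=[PanelEntry(name=f"{prefix}{i + 1:02d}", seq="AC" * 10 + "ACGT"[i % 4] * (i + 1))
                     for i in range(n)],
        )

    def test_exact_match_reuses_name(self):
        known = self._known(3)
        mapping = assign_nomenclature([known.entries[1].seq], known)
        assert mapping[known.entries[1].seq] == "Odvi-DRB*02"

    def test_novel_sequences_get_consecutive_serials(self):
        known = self._known(3)
        novel = ["GGGG" + "AC" * 10, "TTTT" + "AC" * 10]
        mapping = assign_nomenclature(novel, known)
        assert [mapping[s] for s in novel] == ["Odvi-DRB*04", "Odvi-DRB*05"]

    def test_twelve_novel_after_eighteen_known_reach_serial_thirty(self):
        known = self._known(18)
        novel = ["ACGT" * 5 + "ACGT"[i % 4] * (i + 30) for i in range(12)]
        mapping = assign_nomenclature(novel, known)
        assert mapping[novel[0]] == "Odvi-DRB*19"
        assert mapping[novel[-1]] == "Odvi-DRB*30"

    def test_duplicate_known_names_rejected(self):
        with pytest.raises(ValueError):
            AllelePanel(locus="X", entries=[PanelEntry("X*01", "AAAA"), PanelEntry("X*01", "CCCC")])


class TestMendelianConsistency:
    def _sample(self, genos):
        return PopulationSample(
            loci=["L"],
            individuals=list(genos),
            genotypes={k: {"L": tuple(sorted(v))} for k, v in genos.items()},
        )

    def _ped(self, rows):
        return pd.DataFrame(rows, columns=["individual", "sire", "dam"])

    @pytest.mark.parametrize(
        "sire,dam,offspring,consistent",
        [
            (("A", "B"), ("C", "D"), ("A", "C"), True),
            (("A", "A"), ("B", "B"), ("A", "B"), True),
            (("A", "A"), ("B", "B"), ("A", "A"), False),
            (("A", "B"), ("A", "B"), ("A", "A"), True),  # A transmissible from each
            (("A", "B"), ("C", "D"), ("A", "B"), False),  # both from the sire only
        ],
    )
    def test_bipartite_transmission_rule(self, sire, dam, offspring, consistent):
        sample = self._sample({"s": sire, "d": dam, "o": offspring})
        ped = self._ped([("s", "", ""), ("d", "", ""), ("o", "s", "d")])
        flags, frac = mendelian_consistency(sample, ped)
        assert flags["o"] is consistent

    def test_fraction_over_checked_offspring(self):
        sample = self._sample({
            "s": ("A", "B"), "d": ("C", "D"),
            "o1": ("A", "C"), "o2": ("B", "D"), "o3": ("A", "A"),
        })
        ped = self._ped([("s", "", ""), ("d", "", ""), ("o1", "s", "d"), ("o2", "s", "d"), ("o3", "s", "d")])
        _, frac = mendelian_consistency(sample, ped)
        assert frac == pytest.approx(2 / 3)


class TestNoiselessRecovery:
    def test_calls_equal_truth_without_noise(self):
        from dataclasses import replace

        cfg = default_config(seed=5, n_individuals=30)
        cfg = replace(cfg, error_rate_per_base=0.0, chimera_rate=0.0, short_read_rate=0.0,
                      singleton_noise_rate=0.0, depth_mean=500.0,
                      het_balance_alpha_beta=(5000.0, 5000.0))
        ped, sample, truth = simulate_pedigree(20, 1, seed=5, config=cfg, offspring_per_generation=10)
        reads, truth = simulate_reads(sample, cfg, truth=truth)
        seqs = {loc: {a.name: a.seq for a in cfg.allele_panel_per_locus[loc]} for loc in cfg.loci}
        founders = set(ped.loc[(ped["sire"] == "") & (ped["dam"] == ""), "individual"])
        for loc in cfg.loci:
            fwd, rev = cfg.primers[loc]
            tables = [
                filter_merged_reads(reads[(i, loc)], fwd, rev, min_len=290, individual_id=i, locus=loc)
                for i in sample.individuals
            ]
            calls, panel, _ = genotype_population(tables, pedigree=ped, external=founders, locus=loc)
            name2seq = {e.name: e.seq for e in panel.entries}
            for c in calls:
                assert c.status in ("homozygote", "heterozygote")
                truth_seqs = tuple(sorted(seqs[loc][a] for a in truth.genotypes[c.individual_id][loc]))
                got = tuple(sorted(name2seq[a] for a in (c.allele_1, c.allele_2)))
                assert got == truth_seqs
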