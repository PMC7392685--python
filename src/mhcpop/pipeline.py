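"""The umbrella pipeline: simulate -> filter -> genotype -> stats -> tests.

Each stage writes its intermediate artifact under the configured output
directory and contributes to a combined report: the called allele panel per
locus, genotype calls, diversity and neutrality statistics per cohort,
HWE exact-test p-values per cohort, the two-locus genotypic LD test, and the
dN/dS summary.  Reported p-values are unadjusted for multiple testing.
Bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .caller import AllelePanel, Thresholds, genotype_population, mendelian_consistency
from .config import PipelineConfig, default_pipeline_config
from .core import PopulationSample
from .dnds import panel_dnds
from .popgen import (
    GenotypeArray,
    McmcSettings,
    effective_population_size,
    frequencies,
    hwe_probability_test,
    hwe_score_tests,
    ld_genotypic_test,
)
from .read_filter import filter_merged_reads
from .seqstats import AlignedPanel, diversity, neutrality_stats, translate_and_collapse
from .simulate import SimulationConfig, default_config, simulate_pedigree, simulate_reads

__all__ = ["run_pipeline", "calls_to_sample", "panel_for_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def calls_to_sample(calls_by_locus: dict[str, list], cohorts: Optional[dict[str, str]] = None) -> PopulationSample:
    """Assemble resolved genotype calls at one or two loci into a sample
    restricted to individuals resolved at every locus."""
    loci = list(calls_by_locus)
    per_ind: dict[str, dict[str, tuple[str, str]]] = {}
    for locus, calls in calls_by_locus.items():
        for c in calls:
            if c.status in ("homozygote", "heterozygote"):
                per_ind.setdefault(c.individual_id, {})[locus] = tuple(sorted((c.allele_1, c.allele_2)))
    individuals = sorted(i for i, g in per_ind.items() if len(g) == len(loci))
    return PopulationSample(
        loci=loci,
        individuals=individuals,
        genotypes={i: per_ind[i] for i in individuals},
        cohorts={i: (cohorts or {}).get(i, "") for i in individuals},
    )


def panel_for_cohort(panel: AllelePanel, sample: PopulationSample, locus: str) -> AlignedPanel:
    """Aligned panel of the alleles carried by a (cohort) sample, with
    multiplicities equal to allele copy counts among its individuals."""
    copies: dict[str, int] = {}
    for ind in sample.individuals:
        for a in sample.genotypes[ind][locus]:
            copies[a] = copies.get(a, 0) + 1
    by_name = panel.by_name()
    names = [n for n in panel.names() if n in copies]
    return AlignedPanel(
        locus=locus,
        names=names,
        seqs=[by_name[n].seq for n in names],
        multiplicities=[copies[n] for n in names],
    )


def _stats_block(aligned: AlignedPanel) -> dict:
    div = diversity(aligned)
    neu = neutrality_stats(aligned)
    return {
        "n": div.n,
        "sites": div.L,
        "S": div.S,
        "k": round(div.k, 4),
        "pi": round(div.pi, 4),
        "hd": round(div.hd, 4),
        "tajima_d": round(neu.tajima_d, 4) if not np.isnan(neu.tajima_d) else None,
        "fu_li_dstar": round(neu.fu_li_dstar, 4) if not np.isnan(neu.fu_li_dstar) else None,
        "fu_li_fstar": round(neu.fu_li_fstar, 4) if not np.isnan(neu.fu_li_fstar) else None,
        "fus_fs": round(neu.fus_fs, 4) if not np.isnan(neu.fus_fs) else None,
        "bands": neu.bands,
    }


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    sim_config: Optional[SimulationConfig] = None,
    out_dir: Optional[str] = None,
) -> dict:
    """Run every stage on synthetic data and return the combined report.

    Stage failures raise :class:`PipelineError` naming the stage.
    """
    config = config or default_pipeline_config()
    out = out_dir or config.out_dir
    os.makedirs(out, exist_ok=True)
    report: dict = {"seed": config.seed, "loci": [l.name for l in config.loci]}

    # --- simulate ---------------------------------------------------------
    try:
        sim = sim_config or default_config(seed=config.seed, n_individuals=config.n_individuals)
        ped, truth_sample, truth = simulate_pedigree(
            n_founders=config.n_founders,
            n_generations=config.n_generations,
            seed=config.seed,
            config=sim,
        )
        reads, truth = simulate_reads(truth_sample, sim, truth=truth)
        mio.write_pedigree(ped, os.path.join(out, "pedigree.csv"))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    # --- filter -----------------------------------------------------------
    try:
        thresholds = Thresholds(homo=config.homo_threshold, het_low=config.het_low_threshold)
        tables = {l.name: [] for l in config.loci}
        for l in config.loci:
            for ind in truth_sample.individuals:
                table = filter_merged_reads(
                    reads[(ind, l.name)],
                    fwd_primer=l.fwd_primer,
                    rev_primer=l.rev_primer,
                    min_len=l.min_merged_length,
                    max_mismatch=config.primer_max_mismatch,
                    individual_id=ind,
                    locus=l.name,
                )
                tables[l.name].append(table)
        report["read_filtering"] = {
            l.name: {
                stage: int(sum(t.stage_counts[stage] for t in tables[l.name]))
                for stage in ("input", "after_primer", "after_length", "after_singleton")
            }
            for l in config.loci
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("filter", e) from e

    # --- genotype ---------------------------------------------------------
    try:
        calls_by_locus, panels = {}, {}
        external = set(ped.loc[(ped["sire"] == "") & (ped["dam"] == ""), "individual"])
        for l in config.loci:
            calls, panel, call_report = genotype_population(
                tables[l.name],
                pedigree=ped,
                external=external,
                thresholds=thresholds,
                locus=l.name,
                maf_numerator=config.maf_numerator,
            )
            calls_by_locus[l.name] = calls
            panels[l.name] = panel
            mio.write_calls(calls, os.path.join(out, f"calls_{l.name}.csv"))
            mio.write_panel(
                panel,
                os.path.join(out, f"panel_{l.name}.fasta"),
                os.path.join(out, f"panel_{l.name}.csv"),
            )
            report.setdefault("genotyping", {})[l.name] = call_report
        sample = calls_to_sample(calls_by_locus, cohorts=truth_sample.cohorts)
        # parents without resolved calls are explicitly unknown for the check
        known_inds = set(sample.individuals)
        ped_checked = ped.copy()
        for col in ("sire", "dam"):
            ped_checked.loc[~ped_checked[col].isin(known_inds), col] = ""
        flags, frac = mendelian_consistency(sample, ped_checked)
        report["pedigree_consistency"] = {
            "checked": len(flags),
            "fraction_consistent": round(frac, 4) if flags else None,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("genotype", e) from e

    # --- stats ------------------------------------------------------------
    try:
        report["statistics"] = {}
        cohort_labels = [c for c in ("founding", "final") if any(v == c for v in sample.cohorts.values())]
        for l in config.loci:
            locus_stats = {}
            for label in cohort_labels:
                sub = sample.cohort(label)
                if len(sub.individuals) < 2:
                    continue
                aligned = panel_for_cohort(panels[l.name], sub, l.name)
                locus_stats[label] = _stats_block(aligned)
                if l.exon is not None:
                    # exon alleles inherit copies from their extended parents
                    exon_aligned_names, exon_seqs, exon_mult = [], [], []
                    copies: dict[str, int] = {}
                    for ind in sub.individuals:
                        for a in sub.genotypes[ind][l.name]:
                            copies[a] = copies.get(a, 0) + 1
                    exon_panel_obj, mapping = mio.extract_exon(panels[l.name], l.exon)
                    for e_entry in exon_panel_obj.entries:
                        m = sum(copies.get(parent, 0) for parent in mapping[e_entry.name])
                        if m:
                            exon_aligned_names.append(e_entry.name)
                            exon_seqs.append(e_entry.seq)
                            exon_mult.append(m)
                    if len(exon_aligned_names) >= 2:
                        locus_stats[f"{label}_exon"] = _stats_block(
                            AlignedPanel(l.name + "_exon", exon_aligned_names, exon_seqs, exon_mult)
                        )
            # panel-level dN/dS on the coding sequence
            entries = panels[l.name].entries
            if len(entries) >= 2:
                if l.exon is not None:
                    exon_panel_obj, _ = mio.extract_exon(panels[l.name], l.exon)
                    coding = AlignedPanel(l.name, [e.name for e in exon_panel_obj.entries],
                                          [e.seq for e in exon_panel_obj.entries])
                else:
                    coding = AlignedPanel(l.name, [e.name for e in entries], [e.seq for e in entries])
                trimmed = [s[: len(s) - len(s) % 3] for s in coding.seqs]
                coding = AlignedPanel(coding.locus, coding.names, trimmed)
                dnds = panel_dnds(coding)
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", UserWarning)  # stops counted below
                    protein_panel, collapse = translate_and_collapse(coding)
                locus_stats["dnds"] = {
                    "dn_ds": round(dnds["dn_ds"], 4) if not np.isnan(dnds["dn_ds"]) else None,
                    "mean_dn": round(dnds["mean_dn"], 5),
                    "mean_ds": round(dnds["mean_ds"], 5),
                    "n_nucleotide_alleles": coding.n_rows,
                    "n_protein_alleles": protein_panel.n_rows,
                    "n_with_internal_stop": sum("*" in s.rstrip("*") or s.endswith("*") for s in protein_panel.seqs),
                }
            report["statistics"][l.name] = locus_stats
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", e) from e

    # --- tests ------------------------------------------------------------
    try:
        settings = McmcSettings(seed=config.seed + 97)
        report["hwe"] = {}
        for l in config.loci:
            locus_hwe = {}
            for label in cohort_labels:
                sub = sample.cohort(label)
                if len(sub.individuals) < 2:
                    continue
                arr = GenotypeArray.from_sample(sub, l.name)
                prob = hwe_probability_test(arr, settings)
                exc = hwe_score_tests(arr, settings, "excess")
                def_ = hwe_score_tests(arr, settings, "deficit")
                locus_hwe[label] = {
                    "probability": round(prob.p, 4) if prob.applicable else None,
                    "excess": round(exc.p, 4) if exc.applicable else None,
                    "deficit": round(def_.p, 4) if def_.applicable else None,
                    "method": prob.method,
                }
            report["hwe"][l.name] = locus_hwe
        if len(config.loci) == 2:
            la, lb = (l.name for l in config.loci)
            founding = sample.cohort("founding") if "founding" in cohort_labels else sample
            ld = ld_genotypic_test(founding, la, lb, settings)
            ld_all = ld_genotypic_test(sample, la, lb, settings)
            report["ld"] = {
                "founding": {"p": round(ld.p, 4) if ld.applicable else None, "se": round(ld.se, 4) if ld.applicable else None,
                             "n": len(founding.individuals)},
                "all": {"p": round(ld_all.p, 4) if ld_all.applicable else None, "se": round(ld_all.se, 4) if ld_all.applicable else None,
                        "n": len(sample.individuals)},
            }
        report["notes"] = "p-values are unadjusted for multiple testing"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("tests", e) from e

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
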