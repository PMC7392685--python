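#!/usr/bin/env python
"""Diversity, neutrality and selection statistics per locus and cohort.

For each locus and cohort (founding vs final) computes S, k, pi, Hd and the
neutrality tests (Tajima's D, Fu & Li's D*/F*, Fu's Fs) on the called allele
panel weighted by allele copies among cohort members; for the non-classical
locus the statistics are computed for both the extended amplicon and the
exon; and for each locus the pathway-method dN/dS with the codon-by-codon
cumulative substitution profile.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np
import pandas as pd

from mhcpop.dnds import cumulative_dnds_profile, panel_dnds
from mhcpop.io import extract_exon, read_calls, read_panel
from mhcpop.pipeline import calls_to_sample, panel_for_cohort
from mhcpop.seqstats import AlignedPanel, diversity, neutrality_stats, translate_and_collapse

EXONS = {"DOB": (45, 315)}  # 270 bp exon inside the 360 bp amplicon


def stats_row(aligned: AlignedPanel) -> dict:
    d = diversity(aligned)
    n = neutrality_stats(aligned)
    return {
        "n": d.n, "sites": d.L, "S": d.S, "k": round(d.k, 3),
        "pi": round(d.pi, 4), "Hd": round(d.hd, 3),
        "tajima_D": round(n.tajima_d, 3), "fu_li_Dstar": round(n.fu_li_dstar, 3),
        "fu_li_Fstar": round(n.fu_li_fstar, 3), "fus_Fs": round(n.fus_fs, 3),
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", default="results/genotypes")
    ap.add_argument("--truth-dir", default="results/synthetic")
    ap.add_argument("--out-dir", default="results/statistics")
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    truth = pd.read_csv(os.path.join(args.truth_dir, "true_genotypes.csv"))
    cohorts = dict(zip(truth["individual"], truth["cohort"].fillna("")))

    rows = []
    for locus in ("DRB", "DOB"):
        calls = read_calls(os.path.join(args.in_dir, f"calls_{locus}.csv"))
        panel = read_panel(os.path.join(args.in_dir, f"panel_{locus}.fasta"),
                           os.path.join(args.in_dir, f"panel_{locus}.csv"), locus=locus)
        sample = calls_to_sample({locus: calls}, cohorts=cohorts)
        for label in ("founding", "final"):
            sub = sample.cohort(label)
            if len(sub.individuals) < 2:
                continue
            aligned = panel_for_cohort(panel, sub, locus)
            rows.append({"locus": locus, "cohort": label, "region": "amplicon", **stats_row(aligned)})
            if locus in EXONS:
                exon_panel, mapping = extract_exon(panel, EXONS[locus])
                copies = {}
                for i in sub.individuals:
                    for a in sub.genotypes[i][locus]:
                        copies[a] = copies.get(a, 0) + 1
                names, seqs, mult = [], [], []
                for e in exon_panel.entries:
                    m = sum(copies.get(p, 0) for p in mapping[e.name])
                    if m:
                        names.append(e.name), seqs.append(e.seq), mult.append(m)
                if len(names) >= 2:
                    rows.append({
                        "locus": locus, "cohort": label, "region": "exon",
                        **stats_row(AlignedPanel(locus + "_exon", names, seqs, mult)),
                    })

        # selection summary on the coding panel (all called alleles)
        if locus in EXONS:
            coding_panel, _ = extract_exon(panel, EXONS[locus])
            coding = [e.seq for e in coding_panel.entries]
            coding_names = [e.name for e in coding_panel.entries]
        else:
            coding = [e.seq[: len(e.seq) - len(e.seq) % 3] for e in panel.entries]
            coding_names = [e.name for e in panel.entries]
        ap_panel = AlignedPanel(locus, coding_names, coding)
        if ap_panel.n_rows >= 2:
            dnds = panel_dnds(ap_panel)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                prot, _ = translate_and_collapse(ap_panel)
            prof = cumulative_dnds_profile(ap_panel)
            pd.DataFrame({
                "codon": prof["codon"],
                "cum_syn": np.round(prof["cum_syn"], 4),
                "cum_nonsyn": np.round(prof["cum_nonsyn"], 4),
            }).to_csv(os.path.join(args.out_dir, f"cumulative_dnds_{locus}.csv"), index=False)
            print(f"{locus}: {ap_panel.n_rows} nucleotide alleles -> {prot.n_rows} protein alleles; "
                  f"dN/dS = {dnds['dn_ds']:.2f} "
                  f"({'diversifying' if dnds['dn_ds'] > 1 else 'purifying'} selection signal)")

    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(args.out_dir, "diversity_neutrality.csv"), index=False)
    print(table.to_string(index=False))
    print(f"wrote tables to {args.out_dir}")


if __name__ == "__main__":
    main()
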