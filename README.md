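# mhcpop

Amplicon-based MHC genotyping and population-genetic analysis for two-locus
diploid data, with a synthetic-data generator that reproduces the error
structure of deep MiSeq amplicon sequencing.

## The problem

Genotyping major histocompatibility complex (MHC) loci from amplicon
sequencing is harder than ordinary variant calling: a classical class II gene
such as *DRB* can carry dozens of highly diverged alleles, PCR produces
chimeric recombinants of an individual's two true alleles, primer-site
mutations cause allele-specific amplification dropout, and per-base sequencing
error creates clouds of near-true sequences.  This package implements the
full calling procedure used in wildlife MHC surveys of pedigreed populations
(the motivating system is a fenced white-tailed deer herd genotyped at the
classical *MHC-DRB* and non-classical *MHC-DOB* second exons), plus the
population-genetic analyses run on the resulting genotypes.  It is aimed at
molecular ecologists genotyping one or two MHC loci in a few hundred
individuals with deep per-individual read coverage.

## What it computes

**Allele calling.** After merging, reads are filtered (corrupt primers,
merged length < 290 bp, within-individual singletons) and collapsed into a
ranked variant table.  With c₁, c₂ the two top counts and r = c₂/(c₁+c₂):
r < 0.10 calls a homozygote (the 90:10 rule; typical homozygote noise is
~99:1), 0.35 ≤ r ≤ 0.50 calls a heterozygote (50:50 to 65:35; typical balance
~58:42), and the band 0.10 ≤ r < 0.35 is ambiguous and is resolved through a
validated allele panel, Mendelian consistency with the pedigree, or external
(Sanger) validation.  Lower-ranked sequences are screened as single-crossover
PCR chimeras; alleles below the population minimum frequency 5/(2n) are
removed unless independently validated.

**Sequence statistics.** Segregating sites S, mean pairwise differences k,
nucleotide diversity π = k/L, haplotype diversity Hd = n/(n−1)(1 − Σpᵢ²),
Tajima's D, Fu & Li's D* and F* (total mutations η, singletons η_s), and
Fu's Fs from the exact Ewens sampling formula (unsigned Stirling numbers in
exact rational arithmetic).  Pairwise p-distances and Poisson-corrected
amino-acid distances d = −ln(1−p).  Synonymous/nonsynonymous substitution
counting by the classical pathway method with Jukes–Cantor correction,
panel-level dN/dS (mean dN over pairs / mean dS over pairs) and the
codon-by-codon cumulative substitution profile.

**Genotype tests.** Exact Hardy–Weinberg tests conditional on allele counts
(the Levene distribution): the probability test and one-sided heterozygote
excess/deficit score tests, by exhaustive enumeration of genotype arrays
where feasible and otherwise by the Guo–Thompson Markov chain
(dememorization/batches/iterations = 1000/100/1000 by default, batch-means
standard errors).  A genotypic two-locus independence (LD) test: the
G statistic on the genotype contingency table with a permutation null, no
phase assumption.  Effective population size Ne = 4·N_m·N_f/(N_m+N_f).

**Synthetic data.** Diploid two-locus genotypes at given allele frequencies
with tunable inbreeding f and inter-locus D′; pedigrees with Mendelian
inheritance; negative-binomial read depths; Beta-distributed heterozygote
balance; per-base errors, single-crossover chimeras, allele-specific dropout,
short reads and singleton noise — every read group carries a provenance
label so callers can be scored against truth.

## Worked example

```
python analysis/01_simulate.py --seed 1      # cohort of 150, two loci
python analysis/02_genotype.py               # filter + call genotypes
python analysis/03_diversity_selection.py    # diversity/neutrality/dN/dS
python analysis/04_hwe_ld.py                 # exact HWE + LD tests
python analysis/05_method_validation.py      # truth-scored benchmarks
```

With seed 1 the chain prints, among other things:

```
DRB: 150 individuals, 17 alleles; 27 initially ambiguous (18.0%), 0 left unresolved; MAF threshold 1.67%
pedigree consistency of final calls: 100.0% of 80 checkable offspring
HWE DRB founding  (n= 70, mcmc): probability p=0.733, excess p=0.233, deficit p=0.889
LD founding  (n= 70): G=398.6, p=0.550 +- 0.002 -> no evidence of linkage
recovery under default noise: 99.5% of 200 genotypes correct; 11186 chimera variants survived filtering, 100% flagged and 100% ranked below both true alleles
```

Reading this: 18% of individuals landed in the ambiguous 10–35% ratio band
(the hallmark of imbalanced heterozygote amplification) and all were resolved
by the pedigree/validation step; the founding cohort is in Hardy–Weinberg
equilibrium at both loci; the two loci show no genotypic association among
founders; and on truth-labelled data the caller recovers 99.5% of genotypes
while every surviving PCR chimera is detected and out-ranked by the true
alleles.

The same machinery is scriptable (`mhcpop simulate|filter|genotype|stats|test|run-all`)
and importable (`import mhcpop`).

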