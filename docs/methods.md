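# Methods

This note documents the models, conventions and design choices behind
`mhcpop`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate, and the numerical details that
determine edge-case behaviour.

## Ratio-threshold allele calling

Each gene is treated as a single autosomal diploid locus whose alleles are
distinct amplicon haplotypes.  The call is made from the two most frequent
sequences in an individual's filtered, collapsed read tally, using the
second sequence's share of the top two, r = c₂/(c₁+c₂):

| r | call |
|---|------|
| < 0.10 | homozygote |
| 0.10 – <0.35 | ambiguous |
| 0.35 – 0.50 | heterozygote |

The share convention makes the field's ratio notation map directly onto the
thresholds (90:10 → 0.10, 65:35 → 0.35).  The phrase "relative to the first
sequence" could also be read as c₂/c₁; the top-two-share reading is adopted
because it reproduces the ratio notation exactly.  The heterozygote band is
closed at 0.35.  Sequences ranked third and lower never enter calls; they are
only screened as chimeras or errors.

Ambiguous calls are resolved in two passes.  First, individuals covered by an
external validation flag (Sanger-sequenced animals in the motivating design)
are resolved, and the alleles they carry become *validated* panel entries —
external confirmation validates the allele itself, not only the genotype.
When an independently determined genotype is supplied for such an individual
(`external_genotypes`), it takes precedence over the read-ratio call, which
is what Sanger data does in practice and what catches dropout-induced
miscalls in parents.  Second, the remaining ambiguous individuals are
processed in pedigree order (parents first): the call is upgraded to a
heterozygote when the second sequence matches a validated panel allele and
the implied genotype passes the bipartite Mendelian check against the
parents' current calls.  A second sequence recognisable as a single-crossover
chimera of panel alleles downgrades the call to a homozygote; otherwise the
call is left unresolved rather than guessed.

Allele validation evidence, beyond external flags, is parent–offspring
transmission: an allele present in the resolved calls of both members of a
parent–offspring pair is considered validated.  The minimum-allele-frequency
filter removes unvalidated alleles below 5/(2n) (five copies among 2n
genotyped chromosomes), retains validated ones regardless of frequency, and
flags individuals whose call rests on a removed allele; it is applied once,
after resolution, and frequencies are computed from resolved calls only.
Pedigree-inconsistent calls are flagged but retained.

The chimera detector asks whether a candidate equals prefix(a)+suffix(b) or
prefix(b)+suffix(a) of two equal-length parents for some internal split
point, and returns the maximal compatible crossover interval.  It is
symmetric in the parents and refuses candidates identical to either parent.

## Read filtering

Filters apply in the stated order — corrupt primers, merged length, within-
individual singletons — with stage-wise drop accounting so before/after read
counts are reproducible.  "Corrupt primer" means the forward primer absent at
the start or the reverse-complemented reverse primer absent at the end, each
with at most k mismatches (k = 0 by default; the corruption tolerance is not
specified in the motivating study, so it is configurable).  The 290 bp floor
applies to the merged read *before* primer trimming, and the same configured
floor applies to every locus.  Reads are orientation-normalised first: any
read carrying the forward primer in either orientation is flipped to begin
with it.  Singleton removal happens after exact-sequence collapsing, per
individual.  Ranking sorts by descending count with lexicographic
tie-breaking, so tables are deterministic and invariant to input order.

## Sequence statistics

Statistics run on an `AlignedPanel`: equal-length rows with per-row sample
multiplicities (2 per homozygote, 1 per heterozygous carrier; a flag allows
unit multiplicities to analyse the distinct alleles themselves — both modes
are exposed because DnaSP-style analyses are sometimes run either way).  Gap
handling is complete deletion: every column containing a gap in any row is
excluded from S, k, π and the neutrality tests, so π·L = k holds identically.
This choice is material when an allele carries a small in-frame deletion.

Tajima's D uses S and k with the standard a₁…e₂ constants.  Fu & Li's D* and
F* use total mutations η (a column with c states contributes c−1) and
singleton mutations η_s (states with copy count exactly 1), with the
corrected variance constants in the form used by the standard
implementations.  Fu's Fs computes S′ = P(K ≥ K_obs | θ = k) under the Ewens
sampling formula with exact integer Stirling numbers and exact rational
arithmetic (`fractions.Fraction`; θ is the exact rational value of the float
k), then Fs = ln S′ − ln(1−S′) evaluated on the big-integer numerator and
denominator so samples of several hundred chromosomes neither overflow nor
lose the tail.  S′ at 0 or 1 is reported as signed infinity with an overflow
flag; S = 0 statistics are reported as not-available, never as 0.

Significance bands for D*/F* ("*" for p < 0.05, "^" for 0.10 > p > 0.05) use
an approximate interpolated critical-value table, and Tajima's D bands use
fixed approximate cutoffs; the bands are indicative labels, not exact
p-values, and nothing downstream depends on them numerically.

Substitution counting follows the classical pathway method: per-codon
synonymous site fractions (changes to stop codons count as nonsynonymous, so
sites sum to exactly 3 per codon), multi-step codon differences averaged over
all shortest pathways with stop-codon pathways excluded (falling back to all
pathways in the degenerate case where every pathway is blocked), proportions
Jukes–Cantor corrected, and gapped codons skipped.  The panel summary is
mean(dN)/mean(dS) over pairs — the convention of the standard
synonymous/nonsynonymous analysis tools — not the mean of per-pair ratios.
Distances are p-distances with pairwise deletion; amino-acid distances are
Poisson-corrected, d = −ln(1−p).  Maximum-composite-likelihood nucleotide
distances are deliberately not implemented.

## Exact genotype tests

Both HWE tests condition on the observed allele counts; the null is the
Levene distribution, equivalently random pairing of the 2n allele copies
(which is also how the test-suite oracle computes it).  The probability test
sums P(array) over arrays with P ≤ P_obs·(1+10⁻¹²) — the relative tolerance
keeps the observed array itself in the tail under floating point.  The score
tests use the total heterozygote count as the score statistic, the global
form of the heterozygote excess/deficit score tests; ties count in both
tails, so p_excess + p_deficit ≥ 1.

Enumeration is exhaustive when a cheap bound on the array-space size allows
(a vectorized grid enumeration handles the three-allele case; a recursive
enumerator with a 10⁵-array cap handles the rest).  Otherwise a Guo–Thompson
chain runs on the labelled-individual state space with the classic
allele-swap proposal.  On that space the stationary weight 2^H is cancelled
exactly by the proposal asymmetry (a homozygote offers its allele at two
positions), so every valid swap is accepted; this was verified against
exhaustive enumeration.  The Monte Carlo p comes with a batch-means standard
error under the GenePop-style settings (dememorization 1000, 100 batches of
1000; identical seeds reproduce identical p-values).

The LD test builds the locus-A × locus-B genotype contingency table over
individuals resolved at both loci and permutes one locus' genotypes among
individuals — a genotypic test with no phase assumption, since gametic phase
is unobserved.  p uses the add-one permutation estimator.  Cohort membership
("founding" vs later) is an input column, never inferred.  No
multiple-testing adjustment is applied anywhere; reports state p-values raw.

## The synthetic-data generator

The generator reproduces the read-level phenomena the caller must survive,
at the scale of the motivating study: panels shaped like the observed loci
(19 alleles / 85 segregating sites at 250 bp for the classical locus;
11 alleles / 7 sites at 360 bp with a 270 bp exon for the non-classical
locus, exon offset 45 chosen since only the lengths are published); read
depths around 20 000 per individual per locus, negative-binomial with
dispersion 3 (the study reports means, medians and ranges but not a variance,
so dispersion is a free parameter matched to the reported range); per-base
error 0.1%; chimera rate 2% (heterozygotes only — a chimera of identical
templates is the template); heterozygote balance Beta(8.4, 8.4), chosen so
the median top-two share is ≈ 0.42, i.e. the 58:42 balance the ratio rule
anticipates; dropout as a per-allele amplification-efficiency multiplier
(0.25 puts the expected second share at 0.25/1.25 = 0.2, inside the
ambiguous band); short reads and singleton noise at fractions of a percent.
Homozygote second sequences arise from per-base error only — no separate
contaminant model — which at these settings yields homozygote noise nearer
99.9:0.1 than the 99:1 real amplicon data shows; real error profiles are
higher and position-dependent, and nothing downstream depends on this
difference.  FASTQ output uses constant Q37 qualities because the pipeline
never consumes base qualities after merging.

Genotypes follow P(ii) = pᵢ² + f·pᵢ(1−pᵢ), P(ij) = 2pᵢpⱼ(1−f); negative f is
supported at D′ = 0 by direct genotype-matrix sampling, and inter-locus
association places standardized D′ on the (first allele, first allele)
haplotype with marginals preserved, combined with f ≥ 0 as an autozygosity
mixture.  Reads are returned as collapsed (sequence, count, provenance)
records — true-allele, error, chimera, short — and FASTQ expansion is a
writer concern; provenance counts sum to the depth by construction, and
identical seeds give byte-identical output.

What the generator does **not** emulate: selection (variable sites are
random, so dN/dS on synthetic panels carries no biological signal — the
dN/dS tests verify counting, not selection), position-dependent or
context-dependent sequencing error, quality-score structure, index hopping
or cross-contamination, and linkage beyond the single-pair D′ construction.
Passing tests therefore demonstrate that the calling and testing machinery is
correct under a realistic error budget, not that any biological conclusion
transfers to real data.

## Benchmark problem sizes

The benchmark experiments use 200 individuals (half founders, two offspring
generations) at depth 20 000 for recovery and 5 000 for the dropout
experiment; test calibration uses 1000 null datasets of 100 individuals with
three alleles per locus, exact enumeration for every HWE dataset and 199
permutations per LD dataset (the permutation estimator is exactly valid at
any permutation count; headline single-dataset analyses use the full
1000/100/1000 settings).  The dropout recovery rate is scored on the
heterozygotes the ratio rule actually leaves in the ambiguous band; affected
heterozygotes whose balance drifts below 0.10 are miscalled homozygotes by
construction of the rule and are counted separately.  In the dropout
experiment the founders' true genotypes are supplied as external (Sanger
stand-in) genotypes, mirroring the motivating design in which pre-fence
individuals were Sanger-sequenced precisely because dropout corrupts
ratio-based parent calls; the default-noise recovery experiment uses
validation flags only.

## Known limitations

- Fu & Li significance bands are approximate labels (see above).
- The nomenclature assigner serialises novel alleles in frequency order;
  renaming is deterministic only given the stated ordering rule.
- The MAF filter runs once, not iteratively; whether frequencies should be
  recomputed after excluding flagged individuals is left as in the motivating
  procedure.
- `extract_exon` slices a fixed coordinate interval; panels whose alleles
  differ in length (intronic indels) must be aligned first.
- The LD permutation test conditions on single-locus genotype counts; it is
  not a gametic-phase LD estimate.
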