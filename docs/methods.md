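# Methods

This note documents the models, parameter choices and numerical conventions
behind `hybridloh`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Genome model and coordinates

The diploid is represented as a marker map: for every heterozygous SNP, the
integer copy numbers of the two parental alleles `(n_W, n_Y)`. A disomic
heterozygous site is (1, 1); gene conversion, crossover and UPD move copies
between haplotypes without changing the total; CNVs and aneuploidies change
the total. All internal coordinates are 1-based inclusive (the convention of
the standard yeast genome database); BED output/input is converted to/from
0-based half-open at the I/O layer and the conversion is covered by tests.

Default genome: 16 chromosomes with realistic yeast lengths and centromere
positions (total ≈ 12.07 Mb, smallest 230 kb), G+C 0.38, an rDNA locus on
chromosome XII with per-haplotype repeat counts (defaults 123 W, 72 Y).
Marker spacing presets: ~218 bp ("sequencing", ~55,000 markers) and ~923 bp
("array", ~13,000 probes); tests mostly use a miniature three-chromosome
genome at 1 kb spacing for speed. Marker positions sit on a jittered grid
(seeded), so spacing is controlled but not artificially regular.

## Event simulator

Planted events are sampled uniformly per bp unless pinned (consistent with
the absence of pronounced breakpoint hotspots in this system). Conversion
tract lengths are lognormal, parameterized by median — 10 kb for
crossover-associated and 3 kb for unassociated tracts — with shape σ = 0.9;
only the medians are empirically anchored, so σ is configurable. Sampled
events are rejected if they fall within 20 kb of an earlier event
(`min_separation`) or cover fewer than 2 markers (`min_snps`); both are plan
parameters, and pinned coordinates bypass the rejection. Every realized event
is written to a versioned TSV truth ledger that replays onto a fresh genome
to reproduce the mutated genome exactly — the oracle used by all caller
tests.

Read counts: per-site total ~ Poisson(depth × copy/2), allele split binomial
(beta-binomial when overdispersion > 0; default 0 because no dispersion model
is empirically constrained here). `exact=True` produces rounded expectations
for noise-free oracles. Microarray ratios: per-allele probe signal
proportional to targeted-allele copy, optional Gaussian noise, re-centered so
the genome-wide mean is exactly 1. Alkaline fragmentation: cleavage sites as
a Poisson process at the rNMP density (the ribodysgenic condition is ~1/500
per bp), fragments are inter-site gaps, density 0 returns intact molecules.

## LOH caller

RC = allele count / genome-wide mean per-site total. Genotype states by RC
band membership; band edges are inclusive for the heterozygous band so ties
resolve toward heterozygosity (conservative calling).

**Heterozygous band default [0.25, 0.75].** At mean depth 30 the two allele
counts of an unaltered het site are independent Poisson(15) variates (Poisson
total thinned by a fair binomial), so a band of [0.35, 0.65] would classify
only ~57% of het markers — tripping the caller's own >20% unclassifiable
quality gate on every run. [0.25, 0.75] keeps the unclassified fraction below
~10% at depth 30 while remaining unreachable by true homozygous sites, whose
lost allele has RC ≈ 0. Homozygous calls need RC ≥ 0.8 for the retained and
≤ 0.15 for the lost allele. All bands are parameters.

Segmentation: unclassifiable markers are skipped (they do not break
segments); a state change requires ≥ 2 consecutive concordant markers
(`min_run`); isolated single-marker homozygosity is emitted as a flagged
candidate, not a segment break, because single-SNP events are a real but
separately-reported class. Homozygous segments separated by fewer than 10
heterozygous markers (`merge_gap`) merge into one complex event footprint;
the merge rule is a package choice — complex events are defined only
qualitatively (multiple het/hom transitions) in the source material.

Classification: a footprint touching a chromosome's terminal classified
marker is T-LOH, otherwise I-LOH. Terminal events are reported as
`CO/BIR-candidate` because a single surviving colony cannot distinguish a
reciprocal crossover from break-induced replication without the reciprocal
product; a terminal event with an associated interstitial tract is `CO/CON`;
interstitial events are `CON` (single block) or `CON/CON` (complex). The
recipient (lesion-carrying) haplotype is the one whose alleles were lost.
Breakpoints are half-open intervals (last het marker, first hom marker];
tracts starting at a chromosome's first marker get an interval clipped to the
arm start and flagged.

## Structural calls

Copy-number windows default to 1 kb (the marker spacing); normalization uses
the genome-wide *median* per-site total, robust to a few large CNVs. Large
CNVs require the affected haplotype's coverage near 0 (or 2) *and* an
abnormal total, so copy-neutral LOH is never mis-called as a CNV; calls below
5 kb are discarded. UPD/monosomy detection reads whole-chromosome haplotype
loss from the coverage profile (a monosomic chromosome produces no
classifiable LOH tract at all, since the surviving allele's RC is ~0.5);
whole-chromosome LOH events corroborate the retained haplotype.

Translocation prediction: a terminal deletion on one chromosome coupled with
a terminal duplication on another predicts a translocation of size =
(centromere-containing portion retained on the deleted chromosome) +
(duplicated terminal portion). Both breakpoints must lie within 2 kb of an
annotated dispersed repeat (Ty/delta by default); the tolerance is a package
choice ("near" is not quantified in the source). Element orientations are
reported, not enforced.

rDNA repeats: total = 2 × (mean rDNA coverage / mean single-copy coverage);
the haplotype split is proportional to haplotype-specific read fractions at
rDNA-internal SNPs. The estimator is unbiased on simulation (tested across
100 replicates).

## Mutation spectrum

Haplotype linkage uses read co-observations of the mutant base with a
heterozygous marker within 300 bp (the span of short-read fragments);
linkage requires ≥ 2 concordant co-observations and none discordant — the
read-support rule is a package choice. The 5′-flank test counts both strand
orientations per SNV (denominator = 2 × SNVs with both flanks defined) and
compares the observed 5′C fraction to a configurable expectation (default
0.35) by 1-df chi-square. The expectation is a parameter rather than a
derivation from the 38% G+C content because more than one counting convention
is compatible with it (per-orientation C frequency 19%; at-least-one-
orientation 1 − 0.81² ≈ 34%). Substitutions collapse onto six
pyrimidine-anchored classes; spectra are compared by Fisher's exact test for
2×2 tables and chi-square otherwise (choice logged). A 2 bp deletion is a
run deletion when its unit is part of a tandem dinucleotide run of ≥ 2
copies including the deleted copy. Mixed-read partition: haploid-context
mutations are clonal only when strictly above the 0.70 read-fraction
threshold; diploid-context mutations are judged against a 0.5-centered band.

## Rates and enrichment

Rates are n events / (isolates × divisions), with 25 divisions per colony as
the colony-growth constant and 1 division for the first-division assumption;
folds are reported raw and at two significant figures. DSB extrapolation
multiplies visible inter-homolog events by the sister:homolog repair ratio
(default 20). Locus expectation = n T-LOH × genome fraction, tested by 1-df
chi-square with an exact two-sided Poisson alternative also reported (the
two can disagree for small expectations; both are exposed, neither is
privileged).

Breakpoint-element enrichment: per class, breakpoint midpoints within 1 kb
(one marker spacing; breakpoints are intervals, not points) of a class
interval are compared against the expectation from the class's merged padded
footprint via a one-sided Fisher 2×2; a uniform re-placement permutation
p-value is available as an oracle. Correction across classes is Bonferroni
by default (Benjamini–Hochberg by flag). Permutation p-values are discrete
and mildly conservative; the uniformity property test therefore uses a
configuration with many distinct outcome values.

The tandem-repeat finder reports maximal regions ≥ 24 bp consisting of ≥ 2
adjacent copies of a unit of 1–1998 bp (trailing partial copies count toward
the span); regions contained in a smaller-unit region are suppressed so a
dinucleotide run is not re-reported at period 4. It is validated against a
brute-force all-units scan.

## Gel densitometry

Lane profile = row-wise mean over the lane columns minus the average of
equal-width gap windows on both sides (gap width defaults to half the lane
width; single-sided fallback with a warning at image edges); negative values
are clipped to zero and counted. Migration is modeled as linear in
log10(size) — the standard electrophoresis approximation, and the same model
the synthetic generator uses, keeping round-trips well-posed; extrapolation
beyond the ladder is linear on the same scale and monotonicity is enforced.
Ladder peaks are local maxima above a noise floor of 3 median absolute
deviations. Synthetic bands are mass-weighted (staining reports mass) and
Gaussian-smeared. Profile summaries report the modal size (global maximum)
and mass-weighted mean; normalization defaults to the per-lane global
maximum = 1, with per-peak normalization available separately, since either
reading of "each peak normalized to 1" is defensible.

## What the synthetic data does and does not show

The generator reproduces the *marker-level statistics* of a hybrid diploid —
heterozygous density, copy-number footprints of each event type,
binomial/Poisson counting noise, exponential alkaline fragmentation — so
green tests demonstrate that the callers invert the generative model
correctly at realistic depths and event sizes. It does not model read
alignment or mapping artifacts, GC-coverage bias, marker-dropout near repeat
regions, colony lineage structure (events are planted directly, not grown
through divisions), or real rDNA-internal sequence homogenization; recall and
false-positive numbers on real libraries will be somewhat worse than the
simulated ones.

## Problem sizes used by the default test run

Unit tests run on a three-chromosome half-scale genome at 1 kb spacing;
oracle-equivalence and parental-origin checks use the full 16-chromosome
genome at ~12,000 markers with 30–60 planted events per replicate; the
enrichment calibration uses 100 seeds of 120 breakpoints against an
18-class annotation; Monte-Carlo checks use ≥ 10,000 draws. These sizes were
chosen so the entire suite completes in well under a minute while every
statistical assertion retains comfortable margins.
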