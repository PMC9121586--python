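# Methods

## Scan statistic

For a biallelic parental SNP with per-bulk read counts (ref, alt), the
SNP-index of a bulk is alt/(ref+alt) — the mutant-allele read fraction —
and delta(SNP-index) is the high (dark) bulk's index minus the low
(light) bulk's. With the simulator's default polarity the reference
genome is identified with the light parent, so the expected delta at a
fully linked locus under extreme bulking is +1; a `polarity` flag covers
the case where the reference is a third line and the sign convention
flips.

Sites are filtered before any index is computed: base quality < 30,
RMS mapping quality < 30, or read depth < 2 in **either** bulk excludes
a site. The depth rule is applied per bulk (not to the pooled total)
because the SNP-index of a zero-depth bulk is undefined; thresholds are
inclusive-keep (a site exactly at 30 is kept). Coordinates are 1-based
throughout, as in VCF.

## Sliding windows

Windows are 1-based closed intervals [start, start + window - 1]
anchored at 1 and advanced by `step` (defaults 1 Mb / 10 kb); a site
belongs to every window covering its position. Window statistics are
unweighted arithmetic means over member sites (the literal reading of an
"average SNP-index"; no depth weighting). Empty windows are omitted so
plotted curves skip SNP deserts instead of interpolating zeros. The
plotting coordinate is start + window/2 clipped to the chromosome end.
A window's representative depth — used for the confidence-band lookup —
is the mean over member sites of (depth_high + depth_low)/2; one band
per window mirrors the single plotted threshold curve.

With step = window the windows tile the genome disjointly; this
degenerate case is exploited by tests as an exactly checkable property.

## Null confidence bands

Under no QTL, an unlinked marker's two bulks are random draws from the
cross. The band at depth D is built by two-stage Monte-carlo sampling,
10,000 replicates per depth over a grid of depths 1..100:

1. draw `pool_size` genotypes per bulk — F2 dosage ~ Binomial(2, 1/2)
   (i.e. 1/4, 1/2, 1/4 for 0/1/2), RIL 0/2 equally, BC1 0/1 equally;
2. pooled allele frequency p = sum(dosage)/(2 pool_size);
3. alt reads ~ Binomial(D, p) per bulk, SNP-index = alt/D;
4. delta = high - low.

The two stages are kept explicit (genotype sampling, then read sampling)
rather than collapsed into a beta-binomial: the decomposition of
variance into a depth-independent genotype floor and a 1/D read-sampling
term is the procedure's defining feature, and it is what the tests
verify (band half-width shrinks with depth toward the floor, and with
pool size toward zero). Extreme-phenotype selection is deliberately
absent from the null — that is what "no QTL" means at an unlinked
marker.

Bands are nearest-rank empirical quantiles (numpy's `inverted_cdf`) at
(1-level)/2 and 1-(1-level)/2 for levels 0.95 and 0.99. Lookup rounds a
query depth to the nearest grid depth, breaking ties toward the smaller
(wider, more conservative) band, and clamps beyond the grid. Each depth
gets its own seeded RNG stream (`SeedSequence([seed, depth])`), so the
table is reproducible and independent of simulation order. For
pool_size <= 2 and depth <= 3 the full delta distribution is enumerable
exactly; the tests hold the simulator to that oracle within three
Monte-Carlo standard errors.

## Candidate regions

A window is significant when its mean delta lies outside its band.
Overlapping-or-adjacent significant windows of the same sign merge into
one region (insignificant windows in between do not break a run, since
heavily overlapping windows tile the same signal); sign consistency
prevents fusing opposite-effect artifacts. The minimum run length
defaults to 1 and is configurable. Regions export as 1-based TSV and as
0-based half-open BED.

Fine-map interval length between flanking markers is the simple
coordinate difference right - left (no end-inclusive +1), with kb
rounded to the nearest integer — the convention under which markers at
39,531,980 and 39,626,163 bp span 94,183 bp = 94 kb.

## The synthetic experiment

The generator's defaults are the emulated study conditions: 7
chromosomes of 30 Mb (a cucumber-like 2n = 2x = 14 karyotype), one
parental SNP every ~2 kb (~105,000 markers), 3.3 cM/Mb, 278 F2
individuals, extreme bulks of 20 + 20, pooled depth ~ Poisson(20) per
site per bulk (the design targets ~20x coverage), per-read allele error
0.001, and site qualities drawn in [30, 60] so the default filter is
neutral on clean simulated data.

Meiosis: per gamete and chromosome, crossover count ~ Poisson(genetic
length in Morgans), breakpoints uniform, starting phase equiprobable, no
interference and no sex differences — the minimal model with Haldane's
map function r = (1 - e^(-2d))/2, which the tests check directly on
simulated gametes. Recombination is uniform per Mb; real genomes have
pericentromeric suppression, which would widen linkage (and hence
candidate regions) locally.

Phenotype: liability score a(dosage - 1) + d[dosage = 1] + N(0, sigma)
at the causal SNP (always a member of the marker set). Defaults a = 1,
d = 0.6a — the heterozygote leans toward the dark parent, matching an
incompletely dominant locus — and sigma = 1.0. Sigma is the one free
noise scale; 1.0 was chosen so the causal marker explains roughly a
third of the F2 phenotypic variance, the scale reported for a single
major pericarp-color QTL, while keeping bulk selection imperfect enough
to be interesting (bulks are enriched, not fixed, so windowed delta
peaks around +0.6 to +0.8 rather than pinning at 1).

Bulk selection is rank-based on the liability score (top/bottom
`pool_size`, ties broken by stable index order). The real trait was
scored ordinally by eye; rank selection on the latent scale is the
stated stand-in and slightly sharpens selection relative to coarse
binning. With sigma = 0 the three genotype classes separate exactly, the
1:2:1 counts guarantee both homozygote classes exceed 20 of 278, and the
bulks fix for opposite alleles — the fixed-locus limit in which
delta(SNP-index) at the causal SNP equals 1.0 exactly when sequencing
error is also 0.

What passing tests on this generator do **not** show about real data:
no alignment or variant-calling artifacts (the filter rules are tested
as rules, not as error models), no repetitive-sequence mapping bias, no
segregation distortion, uniform marker density, and a single planted
QTL. The generator is the pipeline's verification harness, not a claim
about any particular genome.

## Single-marker scan

Per marker, genotype-class means are fit by least squares against the
grand-mean null: LOD = (n/2) log10(RSS_null/RSS_full),
PVE = 1 - RSS_full/RSS_null. Classes absent from the sample simply drop
out; a constant phenotype returns LOD = PVE = 0; a perfect fit returns
PVE = 1 with infinite LOD. This is a deliberate stand-in for
multiple-QTL interval mapping, adequate for verifying simulated effect
sizes; it is not used for any claim about real populations.

## Expression module

2^-ddCt with the calibrator as an explicit required input: per replicate
dCt = Ct_target - Ct_reference, ddCt = dCt - mean(dCt of calibrator),
fold = 2^-ddCt. The calibrator group's folds have geometric mean 1 by
construction, and folds are invariant to any constant Ct shift — both
are tested identities. The group comparison is a pooled-variance
Student's t-test (two-sided) with Welch behind a flag; zero pooled
variance is an error rather than a fabricated p-value. No amplification-
efficiency (Pfaffl) correction.

## Numerical and engineering choices

- Window means use per-chromosome prefix sums (O(sites + windows));
  tests compare against an O(sites x windows) brute force at 1e-12.
- All site collections are pandas DataFrames with a fixed column schema;
  `PooledVariant`/`BulkCounts` dataclasses are the validated single-site
  atoms.
- VCF input is parsed with pysam; depths always come from per-sample AD
  allelic depths, never the DP field. The writer emits a minimal GT:AD
  VCF 4.2 that round-trips exactly.
- CI tables serialize floats by repr and are re-read with pandas'
  round-trip float parser, so save/load is lossless.
- Every stochastic component takes a single integer seed;
  per-depth/per-stage streams are derived via `SeedSequence` spawn keys,
  so outputs are independent of execution order and bit-reproducible.

## Problem sizes

Default analysis runs use the full design above (~105,000 SNPs, 21,000
windows, 10,000 null replicates x 100 depths); a full scan takes a few
seconds on one core. Test-suite simulations use the same model at
smaller marker densities or chromosome counts where the property under
test does not need the full genome; the end-to-end recovery test runs
the complete default design across 20 seeds.

## Known limitations

- The null band is per-window via its mean depth; no multiplicity
  correction across windows is applied (none is part of the emulated
  procedure), so isolated band-crossings at P<0.05 are expected by
  chance and the P<0.01 band is the region-calling default.
- Windows near chromosome ends are not truncated in their nominal
  [start, end] span (only the midpoint is clipped); with empty-window
  omission this has no effect on statistics.
- Multiallelic sites and indels are skipped, not decomposed.
- The simulator draws marker qualities independently of genotype; it
  cannot exercise quality-vs-allele confounding.
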