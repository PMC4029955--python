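# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behaviour on real cohorts.

## Data model and conventions

Variants are 1-based (VCF convention); windows, BED intervals and
aggregation regions are 0-based half-open, converted at the boundary.
Alleles are coded 0 = ancestral, 1 = derived from the INFO/AA annotation
(a side table can override it). A site whose annotated ancestral allele
matches neither REF nor ALT keeps REF-coding and is flagged
`ancestral_known = False`: it is excluded from iHS (which needs polarity)
but kept for PBS and XP-EHH (which do not). Alleles are taken as
reported; no strand flipping is attempted, since single-platform data
make flipping a merge concern outside this package's scope.

Genetic positions come from a HapMap-format map (position, rate in cM/Mb,
cumulative cM), linearly interpolated between map points and extrapolated
beyond either end at the terminal rate.

All thresholds live in a flat key=value config (`coldscan.config`), CLI
overridable. Defaults: call rate > 0.98, MAF ≥ 0.05, LD r² > 0.1 in
50-SNP windows advanced by 10, PI_HAT > 0.125, 100-kb PBS windows,
200-kb haplotype windows, |iHS| > 2, EHH truncation 0.05, top 1% / 5%
fractions, EASE α = 0.01, painting assignment 0.7, jackknife blocks of
500 SNPs, f3 Z < −2.

## Quality control

Call-rate filtering keeps variants whose non-missing fraction strictly
exceeds the threshold. MAF filtering is inclusive ("at least" 5%).

LD thinning computes genotype-dosage r² on pairwise-complete
observations within 50-SNP windows; of each violating pair the
later-positioned SNP is removed (a deterministic tie-break; the common
tools leave this unspecified). Removals compact the kept list, so full
sweeps repeat until no window contains a violating pair — the output
therefore satisfies the advertised guarantee (no within-window pair above
r²) rather than only a single-pass approximation.

Relatedness uses the method-of-moments IBD decomposition: observed
IBS0/1/2 counts against their expectations given allele frequencies
(estimated from the population subset under test, fixed alleles
excluded), solved sequentially for P(IBD=0,1,2), negatives clamped and
the triple renormalized; PI_HAT = P1/2 + P2. Pruning is iterative within
each population: while any pair exceeds the threshold, remove the
individual with the most over-threshold partners (ties: higher mean
PI_HAT over those partners, then lexicographically smaller id), then
re-estimate frequencies. This removal order is this package's rule; it
minimizes removals for the common duplicate and parent–offspring cases
(a trio resolves to one removal — the child, who has two over-threshold
partners). Fewer than 100 informative SNPs is an error: the estimator is
unstable below that.

## F_ST and PBS

The two-population Weir–Cockerham (1984) estimator with the observed
heterozygosity term is computed per SNP; a multi-locus ratio-of-sums
estimate is also exposed. Correctness is established against an
independently coded nested-ANOVA oracle (alleles within individuals
within populations) that reaches θ̂ through mean squares instead of the
direct component formulas; the two agree to 1e-12 on random instances.

Per-SNP θ̂ (not the ratio of sums) feeds PBS, which is per-locus by
definition. Negative θ̂ is clamped to 0 and values are capped at
1 − 1e−6 before T = −ln(1 − F_ST), otherwise the transform is undefined;
the clamping is this package's recorded choice, not inherited from any
reference implementation. Windows are fixed-width 100 kb anchored at
coordinate 0, statistic = max per-SNP PBS, empty windows dropped, SNP
counts kept for density binning. PBS windows get no minimum-SNP filter,
but their counts feed the same percentile machinery as the haplotype
windows.

## EHH, iHS, XP-EHH

EHH at step t from a core is the fraction of carrier-haplotype pairs
identical over all SNPs between the core and t. The implementation
tracks, per pair, the first flanking SNP at which the pair mismatches
(vectorized in 128-SNP chunks); EHH at any step is then the surviving
pair fraction. This is exactly the Σ C(n_h,2)/C(n,2) partition
definition, verified against a string-hashing oracle in the tests.

iHH integrates EHH over cM by trapezoid from the implicit core point
(0, 1), truncated at the first SNP where EHH < 0.05; that SNP is included
as the final vertex (no interpolation of the exact crossing — simple and
consistent with widespread practice; a config key). A core is undefined
when EHH never reaches the threshold before the chromosome end, or when
any adjacent-SNP physical gap inside the integrated span exceeds 200 kb;
the gap rule is a recorded decision for array data with coverage holes.

iHS = ln(iHH_A/iHH_D) at polarized SNPs with MAF ≥ 0.05, standardized
within 20 equal-width derived-frequency bins on [0.05, 0.95]; bins with
fewer than 50 defined scores merge into their right neighbour (the last
bin merges left). Sweeps on the derived allele give negative raw scores.

XP-EHH computes EHH over all haplotypes of each population and truncates
both integrals where the EHH of the pooled two-population sample drops
below 0.05, so test and reference integrate over the same span; scores
ln(iHH_test/iHH_ref) are standardized genome-wide.

Window statistics: fraction of |iHS| > 2 and maximum XP-EHH in 200-kb
windows, windows with fewer than 10 scored SNPs dropped. The 10-SNP
minimum is deliberately below the ~20-markers-per-window density of a
typical array so it acts as a guard, not a filter.

## Window ranking

Windows are grouped into equal-occupancy bins by SNP count (deciles by
default; the effective bin count is capped so every bin holds at least 20
windows, collapsing to a single bin on small tables — within-bin
percentiles are meaningless otherwise). Within a bin the percentile is
rank/bin-size with ties sharing the maximum rank, so the bin maximum is
always exactly 1.0 and a table of identical statistics is all ties at
1.0. Top-1% windows are candidates; for iHS an outgroup table on the
same grid can exclude candidates that are also top-5% in the outgroup.
Whether the outgroup exclusion also applies to XP-EHH is a config switch,
off by default.

Sharing between two populations is the fraction of one table's top-1%
windows found in the other's top 5%. Candidate windows aggregate into
3-Mb regions (anchored at 0) by window start; the max-count region is the
densest signal cluster. Cross-test overlap between the 100-kb PBS grid
and the 200-kb haplotype grid uses interval intersection. The seed-gene
test is a one-sided Fisher exact on windows containing at least one seed
gene, top set vs rest of the ranked universe.

## Enrichment (EASE)

Terms attach to windows through genes, deduplicated per window, so a
positional cluster of same-term genes contributes one window. The EASE
score is the one-tailed hypergeometric tail recomputed with the overlap
reduced by one (k → k−1, margins fixed); k ≤ 1 forces p = 1, and
ease_p ≥ fisher_p always. The universe is the ranked window set of the
test at hand (the windows that survived the min-SNP filter), not the
whole genome — it is the set the top windows were actually drawn from.
Benjamini–Hochberg q-values are implemented but off by default; the
uncorrected EASE ≤ 0.01 is the calling rule. Null calibration over
random top-window draws confirms the call rate stays at or below nominal
(EASE is conservative by construction).

## Copying-model painting

A recipient haplotype is a haploid Li–Stephens mosaic of donor
haplotypes: hidden state = donor, switch probability 1 − exp(−ρ·ΔcM)
between consecutive SNPs followed by a uniform re-draw (self included),
emission match probability 1 − θ. This is a deliberately simplified
copying model — no per-donor copy-length weighting, no chunk counts —
whose job is the assignment rule and the regional tail test; it is not a
reimplementation of the full chromosome-painting machinery. θ defaults
to 0.5/(n_donors + 0.5), ρ initializes at 1 per cM, both configurable.

The forward–backward posterior, summed over donors within each ancestry,
is the expected copying probability per SNP (validated to 1e−9 against
exhaustive path enumeration on small instances). A SNP is assigned to an
ancestry only when its probability strictly exceeds 0.7; ties and
anything at or below the threshold are "undecided".

ρ is estimated by EM (default 10 fixed steps): the E-step computes the
posterior probability of a re-draw event per interval, the M-step
maximizes the expected Bernoulli log-likelihood in ρ by bounded scalar
optimization; the data likelihood is non-decreasing across steps and the
parameter is recovered within a factor of two on model-generated data.

Donor selection takes samples whose ancestry coefficient for one
component is ≥ 0.99 and whose cluster label agrees; coefficients and
clusters are inputs (ancestry-matrix estimation is out of scope).

The regional test aggregates a donor's expected copying probability over
SNPs in a candidate region and compares it against same-width regions
tiled genome-wide (the queried region excluded from the tiling, included
in the count), reporting the empirical p and the 5% tail threshold.
Region-level tiling is this package's choice of null; the alternative
(SNP-level resampling) ignores the local correlation of copying
probabilities and would be anti-conservative.

## f3 with block jackknife

Per SNP, f3 = (c − a)(c − b) − ĥ_C/m_C where ĥ_C = m_C/(m_C − 1)·2c(1−c)
is the unbiased heterozygosity of the target and m_C its sampled
chromosome count — the standard finite-sample correction of the
Reich/Patterson estimator family, validated here by simulation
(unadmixed drifted targets give positive f3; a 50/50 mixture of diverged
sources gives strongly negative f3) rather than asserted as any
particular tool's exact code. An infinite-n mode disables the correction
and reduces the estimator to the plug-in moment. SNPs with under two
sampled chromosomes in any population, or fixed identically in all
three, are skipped.

Standard errors come from a weighted delete-one-block jackknife over
contiguous 500-SNP blocks (unequal defined-SNP counts weight the
pseudovalues); Z = f3/SE, admixed if Z < −2. Identical block means give
a degenerate SE, floored at machine epsilon and flagged rather than
producing a spurious Z. Note the jackknife variance itself carries
χ²-type noise of order sqrt(2/n_blocks), which matters when comparing it
against analytic expectations.

## The simulator

`coldscan.sim` generates the regimes the pipeline is designed for:

- **Drift.** Per SNP, an ancestral frequency p is drawn from a Beta
  (default Beta(1,1) rescaled into [0.05, 0.95] — a flat, array-like
  common-SNP spectrum with no monomorphic sites), then each population's
  frequency from the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F); F = 0
  returns p exactly. Default F = 0.05 per population, a typical
  within-continent divergence.
- **Background LD.** Off by default for frequency-based statistics
  (per-site independence is sufficient and fast). With
  `copying_smoothing` each haplotype is re-drawn as a mosaic of 20
  founders (switch rate 5/cM, per-site flip 0.002), giving the non-trivial
  EHH decay the haplotype scans require: with independent sites every
  sweep is trivially detectable, which would make the power tests
  meaningless.
- **Sweeps.** The nearest variant to the requested position whose current
  derived frequency does not exceed the target becomes the core; a
  fraction `target_freq` of the population's haplotypes receive the
  derived core allele and are overwritten over ±core_len_cM by copies of
  one carrier haplotype with per-SNP copy error ε = 0.002 (preventing
  degenerate infinite iHH on finite panels). Default core length 0.5 cM,
  the scale of a recent strong sweep.
- **Relatives.** Duplicates copy both haplotypes; parent–offspring
  children receive one Haldane-recombined gamete from each parent.
- **Admixture.** Mosaic individuals with exponential tract lengths of
  mean 100/g cM, donor drawn per tract with the stated proportion; truth
  tracts tile each haplotype exactly (recorded in bp).
- **Annotations.** Genes tile the chromosome; GO terms attach to runs of
  adjacent genes to exercise the positional-clustering correction.

Everything is driven by one `numpy` Generator seeded from the config, so
a fixed seed reproduces panels byte-for-byte.

What the simulations do **not** emulate: realistic site-frequency spectra
and singletons (array-like common variants only), variable recombination
and mutation rates, background selection, phasing error, genotyping
error beyond uniform missingness, and multi-chromosome genomes (all
statistics are per-chromosome and concatenate naturally, but the default
panels are single-chromosome). Passing power tests therefore show the
statistics respond to the planted signals under calibrated drift and
LD — not that detection rates transfer quantitatively to any particular
real cohort.

## Problem sizes in the test and acceptance runs

The shipped checks run at desk scale, chosen to keep each suite within a
few minutes while leaving the conclusions qualitative: sweep-power
replicates use 20 diploids, 5,000 SNPs on 10 Mb (about 40 chromosomes
and 100 SNPs per 200-kb window, matching the regime where haplotype
scans retain power); PBS branch recovery uses three populations of 20 at
5,000 SNPs; f3 uses 25 samples per group at 20,000 SNPs; QC relatedness
uses 20 samples at 20,000 SNPs. Detection in the power tests means a
top-1% window overlapping the swept tract (core ± core length): the
sweep's shared haplotype spans the whole tract, so adjacent windows
inside it are correct detections, and at 50 windows per replicate the
top-1% rule flags only one or two windows genome-wide.

## Known limitations

- The haplotype-scan engine is O(pairs × extent) per core; panels of
  hundreds of thousands of SNPs and large samples will want chunked
  parallelism (results are independent of execution order by design).
- PI_HAT uses plug-in allele frequencies without the small-sample
  expectation corrections of the classic tools; with very small
  populations (≲12 samples) unrelated pairs occasionally cross lenient
  thresholds.
- The painting model ignores donor-set imbalance: ancestries with more
  donor haplotypes receive proportionally more prior mass. Balanced donor
  panels (as selected by the Q ≥ 0.99 rule) make this immaterial, but
  heavily skewed panels would need per-population prior reweighting.
- The EM for ρ treats θ as fixed; joint estimation is out of scope.
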