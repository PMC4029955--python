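# coldscan

Genome-wide scans for recent positive selection in structured populations,
built for SNP-array cohorts: quality control with iterative relatedness
pruning, allele-frequency differentiation scans (Weir–Cockerham F_ST and
the population branch statistic), extended-haplotype-homozygosity scans
(iHS and XP-EHH) with density-binned empirical window ranking,
window-count GO enrichment (EASE), Li–Stephens copying-model ancestry
painting of candidate regions, and the three-population f3 admixture test
with block-jackknife errors. A truth-tracking simulator generates phased
panels with known drift, sweeps, relatives and admixture tracts, so every
stage is testable end to end without external data.

The intended user is a population geneticist who wants the classic
selection-scan toolchain — the kind of analysis run on cohorts of a few
hundred genotyped individuals from several diverged populations — as one
reproducible, scriptable pipeline with explicit, configurable thresholds.

## The statistics

**F_ST and PBS.** Pairwise F_ST per SNP uses the Weir & Cockerham (1984)
weighted analysis of variance, θ̂ = a/(a+b+c) from the among-population,
among-individual and within-individual variance components. Branch
lengths T = −ln(1 − F_ST) convert pairwise differentiation into additive
drift; the population branch statistic of test population A against
outgroups B, C is

    PBS_A = (T_AB + T_AC − T_BC) / 2,

the frequency change private to A's branch. The genome is cut into 100-kb
windows and the maximum per-SNP PBS is the window statistic.

**iHS and XP-EHH.** EHH(x) is the probability that two random carrier
haplotypes are identical at every SNP from a core out to genetic distance
x; iHH is its trapezoid integral over cM, truncated where EHH drops below
0.05. iHS = ln(iHH_ancestral/iHH_derived), standardized within
derived-allele-frequency bins; XP-EHH = ln(iHH_test/iHH_reference)
computed over all haplotypes of each population and standardized
genome-wide. Window statistics (200 kb) are the fraction of SNPs with
|iHS| > 2 and the maximum XP-EHH.

**Ranking.** Windows are binned by SNP count into equal-occupancy bins
and ranked within bins, which removes the SNP-density bias of the raw
statistics; the top 1% are candidates, optionally dropping windows that
are also top-5% outliers in an outgroup population (shared, presumably
older, signals).

**Enrichment.** GO terms are attached to windows through their genes with
at most one count per window, and tested with the EASE score — a
one-tailed Fisher exact test recomputed after removing one item from the
overlap — so a single gene cluster inside one swept window cannot drive a
term call.

**Painting.** Phased chromosomes are painted as Li–Stephens mosaics of
donor haplotypes from reference ancestries; the forward–backward
posterior summed per donor population gives an expected copying
probability per SNP, assigned to an ancestry only when it exceeds 0.7.
A regional tail test compares a candidate region's mean copying
probability against same-width regions tiled genome-wide.

**f3.** f3(C; A, B) = E[(c−a)(c−b)] with the finite-sample
heterozygosity correction for the target; block-jackknife Z < −2 flags C
as admixed between relatives of A and B.

## Worked example

Simulate two populations with a hard sweep fixed in POP1, then scan:

```
coldscan --seed 7 --out-dir demo simulate \
    --n-pops 2 --samples-per-pop 20 --n-snps 5000 \
    --sweep POP1:5000000:1.0:0.5
coldscan --out-dir demo scan-xpehh \
    --vcf demo/panel.vcf --gmap demo/genetic_map.txt \
    --labels demo/labels.tsv --test POP1 --ref POP2
```

which prints

```
wrote panel (5000 SNPs, 80 haplotypes) to demo
50 XP-EHH windows for POP1 vs POP2
```

`demo/xpehh_windows_POP1.tsv` then holds one row per 200-kb window with
its SNP count, maximum standardized XP-EHH, density bin and empirical
percentile. On this run the two top-ranked windows (percentile 1.0) are
`1:5000000-5200000` (max XP-EHH 3.52) and `1:4800000-5000000` (3.49),
straddling the planted sweep core at 4,999,820 bp — the sweep's shared
haplotype spans ±0.5 cM, so every window inside that tract is a correct
detection. The panel's truth file (`demo/truth.json`) records the
planted core for comparison.

The equivalent library calls are `simulate_panel`, `xpehh_scan`,
`xpehh_window_stat`, `empirical_percentiles` and `top_windows`; every CLI
subcommand is a thin wrapper over one such function chain.

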