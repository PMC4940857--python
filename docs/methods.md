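# Methods

This note documents the statistical model behind each stage, the
conventions and defaults the package commits to, what the synthetic-data
generators do and do not emulate, and the numerical edge-case rules.

## Coordinates and genomic primitives

All interval arithmetic is 0-based half-open (BED semantics); GTF input
is converted on read. Peaks carry a summit offset; summit-less BED
records default the summit to the interval midpoint. Reproducibility
filtering keeps the peaks of one replicate that overlap a peak of the
other by at least 1 bp (the overlap floor is configurable; nothing in the
analysis motivates a larger default). Summit windows are symmetric
(default 100 bp, clipped at chromosome edges), as are promoter windows
(±500 bp around each TSS; strand does not change the extent, because the
window definition is symmetric).

The distance from a gene to a site set is measured from the TSS to the
nearest covered base of the nearest site (0 when the TSS falls inside a
site), minimized over the gene's transcripts. Measuring from the promoter
edge instead would shift every distance by the flank and change no
ranking; TSS-to-edge is the declared convention. Genes on chromosomes
without any site contribute an infinite distance and stay in CDF
denominators.

## Occupancy and ratios

Counts are normalized to reads per million aligned reads. Counting from a
coverage track sums per-base signal over the region; a track of read 5'
ends therefore yields read counts. Condition contrasts are
log₂((a + c)/(b + c)) with pseudocount c = 1 RPM. The pseudocount keeps
empty regions finite and shrinks ratios of very weak regions toward 0;
c = 1 RPM is small against the typical site RPMs the generators produce
(tens of RPM) and is configurable. Histogrammed "read-depth ratios" are
always these log₂ values. When a gene has several promoters or
transcripts, the region with maximal RPM in the designated reference
(control) sample represents the gene; exact ties go to the 5'-most
region so the choice is deterministic.

## Temporal dynamics

Each site's RPM values are regressed on time in hours by ordinary least
squares, with every replicate observation an independent point
(df = n_obs − 2; for the 2 time point × 2 replicate design, df = 2). The
slope's two-sided t-test p classifies sites at α = 0.05: gained
(slope > 0, p < α), lost (slope < 0, p < α), else stable; a slope of
exactly 0 is stable regardless of p. Fits with zero residual variance
report p = 1e-300 (flat fits report p = 1). A per-site model was chosen
over a genome-wide model with site terms; it is simpler, embarrassingly
parallel, and the classification operates site by site anyway. No
multiple-testing correction is applied by default because the analysis
ranks sites rather than controlling an error rate; a Benjamini–Hochberg
adjustment can be applied downstream of the returned p-values if a
thresholded call set is needed. Within a class, the top fraction
(default 50 %) is selected by ascending p, ties broken by descending
|slope| then site id, taking ⌈n·fraction⌉ sites.

Gained/lost *site counts* between two peak sets are presence/absence
calls: a treated peak with no ≥1-bp overlap in control is gained, and
vice versa. The excess of one count over another is reported as
100·(a − b)/a — percent of the larger count — rounded half away from
zero; this is the only denominator convention that reproduces both
printed comparisons the arithmetic is checked against (51 % and 13 %).

## Motif enrichment

PWMs are position probability matrices over ACGT with a background
(default uniform). Scanning scores every window on both strands with
log₂(p/bg) summed per position (probabilities floored at 1e-9 so a zero
cell scores very low rather than −∞); a window containing N never hits;
a window passing on both strands counts once. The default hit threshold
is 60 % of the PWM's maximum achievable score — a conventional
moderate-stringency choice for short nuclear-receptor/AP1-class motifs —
and is configurable in bits.

Fold enrichment = total observed hits over all site sequences divided by
the mean of total hits over n (default 10) independent scrambles of every
sequence; the denominator is floored at 0.5 so a hit-free null cannot
divide by zero (a floor below one hit keeps any observed signal visible).
The scramble is a seeded uniform permutation of each sequence
(mononucleotide shuffle), preserving base composition exactly. A
dinucleotide-preserving shuffle (Altschul–Erickson Eulerian-path
construction) is available for GC/CpG-sensitive motifs; it preserves the
doublet multiset and first/last characters. The PRNG seed is recorded in
the result.

## Responsive genes and concordance

Fold changes are stored as signed linear folds (+2 = two-fold up,
−2 = two-fold down); log₂ input is converted on read. A gene is
responsive at cutoffs (p*, f*) when adjusted p < p* (strict) and
|fold| ≥ f* (inclusive). Cross-treatment overlap counts genes responsive
in both tables in either direction; concordant means matching fold sign.
Percentages are rounded half away from zero to one decimal — the
convention that reproduces every checked printed cell. The hypergeometric
overlap test is upper-tail, with the universe defaulting to the genes
tested in both tables (configurable; reported p-values are only
meaningful relative to the declared universe).

## Integration

Distance CDFs are evaluated on a log-spaced cutoff grid from 1 kb to
1 Mb (13 points) by default. Enrichment of a target CDF over background
is summarized as the maximum signed vertical gap and the mean signed
difference across cutoffs. Co-occupancy stratification partitions a site
set by ≥1-bp overlap with a mark. Occupancy–expression agreement is
Spearman's rho with average ranks.

The pausing classifier applies to repressed genes only: promoter ratio
> 0 with body ratio < 0 is pausing-consistent; both < 0 is reduced
initiation; anything else (including ratios of exactly 0) is
indeterminate. The distance strata for the gene-body contrast are
< 10 kb (near) and > 100 kb (far), bounds exclusive, with the
intermediate band excluded. The rank-sum test is two-sided; when the
smaller group has ≤ 8 members the p-value is computed by full enumeration
of group assignments on midranks (ties handled exactly), otherwise by the
normal approximation with tie and continuity corrections — at the
boundary the two routes agree to well within 0.01.

## Synthetic data

The generators emulate the structure of a two-drug, two-time-point
nuclear-receptor study: a 2 × 5 Mb genome with 500 non-overlapping genes
(1–3 TSSs each), 2,000 binding sites, duplicate occupancy libraries at
2 h and 48 h, 100-bp site sequences, DE tables for two treatments, and a
200-gene promoter/gene-body pausing scenario. Every generator is a pure
function of (config, seed) — identical inputs give byte-identical
outputs — and emits truth tables sufficient to score downstream calls.

Counts are gamma-Poisson (negative binomial). The `nb_dispersion`
parameter is the biological coefficient of variation of the latent site
intensity — the square root of the edgeR-style dispersion — giving
var = m + (disp·m)², so the count CV approaches `disp` at high depth.
This is the convention under which the package's stated calibration
envelopes (replicate rho ≥ 0.9 at disp ≤ 0.1, ≥ 90 % recovery of 4-fold
shifts at disp 0.05 with two replicates) are simultaneously attainable by
the df = 2 per-site test; with var = m + disp·m² at disp 0.05 that test
has a hard power ceiling near 70 % at any depth. Site base means are
lognormal (median 200 reads per site, log-sd 0.5), representing
reproducible summit windows in deeply sequenced libraries: deep enough
that the late-timepoint counts of 4-fold-lost sites remain informative.

Planted effects: gained/lost sites have their late-time mean multiplied/
divided by the effect size (default 4). Responsive genes get signed
linear folds of magnitude ≈ 4 (never below 2.05) and adjusted p between
1e-12 and 1e-3, so they always pass the (0.01, ±2) cutoffs and planted
counts equal filtered counts exactly; null genes have |fold| ≤ ~1.4 and
uniform p. A configured fraction (default 0.8) of repressed genes gets
one extra site planted within 10 kb of a TSS. Pausing-planted genes
shift promoter RPM by +1.5 log₂ units and body RPM by −1.5 (degradation:
−1.5/−1.5) with lognormal noise of sd 0.2 log₂ units.

What the generators do *not* emulate: read-level data (fragment lengths,
duplicates, mappability), GC or accessibility bias in site placement,
correlated replicate artifacts, genes with fold changes between the two
cutoffs (so the ±1.5 and ±2 filters select identical synthetic sets),
and any coupling between motif content and occupancy strength. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the assumed noise model, not robustness to the full
messiness of real libraries.

## Pipeline and determinism

`run_pipeline` executes quantify → dynamics → motif → concordance →
integration, either from an in-memory simulation or from a directory of
files written by `write_simulation` (and re-read through the standard
parsers). Every output table carries the package version, seed and a
hash of the resolved configuration; a manifest records library versions.
All randomness flows from the single seed through named `SeedSequence`
streams, so a rerun with the same config and seed is byte-identical. The
default problem sizes (2,000 sites, 500 genes, 200 pausing genes, 50
calibration repetitions) run the whole pipeline and its calibration
checks in well under a minute on one CPU.

## Known limitations

* The temporal model is a straight line through two time points; it
  cannot represent non-monotone trajectories (rise-then-fall), and with
  df = 2 its per-site power depends sharply on depth.
* The motif stage ships only a consensus-built AP1-style PWM for the
  synthetic scenario; real analyses should supply a motif library
  (JASPAR files are read directly).
* The hypergeometric overlap p depends entirely on the declared universe;
  no attempt is made to infer the "right" universe from the data.
* The pausing call is a sign-based rule on two ratios; it does not model
  the joint noise of the two assays and offers no per-gene confidence.
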