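# Methods

This note documents the statistical procedures implemented in
`promobind`, the generative model behind its synthetic datasets, the
numerical conventions, and the choices made where the design was
genuinely open. No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Coordinate and binning conventions

All coordinates are 0-based half-open (BED convention); a TSS position
is the first transcribed base. Offsets from a TSS are strand-aware and
signed: on the plus strand `offset = position − tss`, on the minus
strand `offset = tss − position`, so negative is always upstream of the
gene. Peak centers are `floor((start + end) / 2)`; even-width ties
resolve by floor, which keeps everything in integer arithmetic.

Profiles bin offsets into half-open windows `[x, x + 50)` labeled by
their center `x + 25`; offset 0 lies in the bin `[0, 50)`. The default
profiling window is −5000..+3000 bp (160 bins). These conventions are
arbitrary at the ±1-bin level but are pinned by brute-force oracle tests
so every downstream number is reproducible bit-for-bit.

## TSS hygiene and aggregate profiles

Genes with several annotated TSSs are thinned: scanning each gene's
TSSs in genomic order, a TSS is dropped when it lies less than 150 bp
from the previously *retained* TSS of that gene (the boundary case,
exactly 150 bp, is kept).

The mean-signal profile pools every (probe, promoter) pair across all
promoters and averages per bin; an alternative that first averages per
promoter and then across promoters is available via
`per_promoter_mean=True`. Overlapping promoter windows are counted for
both promoters. The percent-bound profile counts, per bin, the fraction
of promoters with at least one peak center in that bin; several centers
of one promoter in one bin count once.

Mode detection looks for strict local maxima (plateau-aware: a run of
equal bins higher than both informative neighbors is one candidate,
resolved to the bin nearest the TSS; boundary maxima count). Candidates
below a prominence threshold — default 10% of the profile's range,
where prominence is the drop from the peak to the higher of the two
bracketing minima — are discarded. Missing bins never form modes and
act as lower neighbors.

Per-promoter matrices keep only promoters with strictly more than 100
informative bins in the −5000..+3000 window ("informative" = the bin
contains at least one probe) and sort rows descending by the supplied
key (typically expression), stable under ties.

## Binding classification and enrichment

A promoter is bound by a factor when at least one peak center lies
within ±2000 bp of its TSS, both endpoints inclusive; one peak may be
assigned to several promoters. OTX2-bound promoters are `single`
(exactly one assigned peak) or `multiple` (two or more); crossing with
the MYC flag yields the classes `single±MYC`, `multi±MYC`, with
`MYC-only` and `unbound` outside the four. Reported percentages use the
natural denominators (all promoters for bound/co-bound fractions, the
OTX2-bound set for single/multiple, the subclass for MYC-within) and
are rounded to one decimal only for display.

Enrichment of MYC among multiple-OTX2 promoters is the exact one-sided
hypergeometric tail `P(X ≥ k)` with population = all promoters,
successes = MYC-bound, sample = multiple-OTX2. The sum runs in log
space (`gammaln` + `logsumexp`), which keeps relative error below
~1e-12 down to magnitudes around 1e-80; agreement with exact rational
arithmetic is verified exhaustively for all instances with N ≤ 60. The
point probability `P(X = k)` is exposed alongside because spreadsheet
workflows (HYPGEOMDIST) historically reported it in place of the tail;
on promoter-scale inputs the two differ by roughly 2×.

## Distance randomization test

For each promoter of class single+MYC, the observed statistic is
|OTX2 center − nearest MYC center| (the nearest rule is the
conservative proximity measure when several MYC peaks are assigned).
The null redraws every OTX2 offset uniformly over the ±2000 bp binding
window, keeping MYC peaks and per-promoter peak counts fixed, and pools
R = 3 randomizations by default; everything is deterministic given the
seed. The uniform-over-the-binding-window redraw *is* the module's null
definition — whether peaks could legitimately be re-placed outside the
window cannot be decided from the binding data alone, so the choice is
pinned here.

Per distance range (defaults `[0,200), [200,400), [400,800),
[800,1600), [1600,∞)`, configurable), a 2×2 table of in/out-of-range
counts is built, with the null column scaled to the observed total and
rounded so the table stays integer-valued, and tested with the
two-sided Fisher exact test (sum-of-smaller-probabilities rule, via
scipy, itself checked against exhaustive enumeration). Because the
observed and null sets are compared after scaling, the test is exact
only conditionally on the pooled null; with R = 3 versus R = 30 the
expected percentages move only within Monte-Carlo error.

## Motif analysis

Scanning is exact string matching, overlaps allowed, both strands by
default; a reverse-complement hit is reported at the forward coordinate
of its first base, and palindromes count once per position. With
`respect_softmask` (the "repeat-masked" variant) a match overlapping
any lowercase base is skipped. Density profiles report, per 50 bp bin
of distance to the anchors, both the percentage of anchors with ≥1
occurrence in that bin and a per-bp occurrence count; TSS anchors use
signed strand-aware offsets, peak-center anchors fold the two flanks
into unsigned distances.

Motif-vs-expression curves stably sort peaks by the expression of their
assigned gene, bin them per 400 peaks (the final partial bin is kept
and flagged), and report per bin the mean expression and the fraction
of peaks containing the motif.

The iterative k-mer search emulates a discriminative motif enumerator
run: per round, all k-mers (k ∈ {6,7,8}) are counted exhaustively on
both strands of foreground and background and scored by
`log2(((c_fg + 1)/(T_fg + 1)) / ((c_bg + 1)/(T_bg + 1)))` — a
pseudocounted relative-frequency ratio. Exhaustive enumeration is exact
at these lengths, so no heuristic search is needed. Under both-strand
counting a k-mer and its reverse complement tie exactly; the scoring
unit is therefore the reverse-complement class (canonical form =
lexicographic minimum), ties between classes break lexicographically,
and the winner is reported in the orientation more frequent on the
foreground forward strand. The winner's occurrences (both orientations)
are masked to N in the foreground and the search repeats, 15 rounds by
default, stopping early with a warning if the foreground is exhausted.
The background is flanking sequence of the peaks (equal width on both
sides, defaulting to the peak width) and is never masked.

## Expression integration

Expression categories are rank quantiles (default five): genes are
stably sorted by log2 expression and split into contiguous groups whose
sizes differ by at most one; ties keep their stable-sorted position.
Percent-bound tables divide bound promoters by all promoters of the
category. Class-wise expression comparisons use Welch's
unequal-variance t-test of multi+MYC against each other class (or
against all others pooled); the pooled-variance test is available via a
flag. Degenerate inputs (zero variance on both sides) are reported as
t = 0, p = 1 when the means agree and NaN otherwise, never an
exception. Genes without expression are excluded and logged, not
imputed.

## The synthetic generator

`generate_dataset` draws, per promoter: OTX2-bound status
(Bernoulli, p = 0.454); for bound promoters a peak count — single with
probability 0.598, otherwise 2 plus a truncated-geometric extra count
(parameter 0.45, total capped at 5; the single/multiple dichotomy is
all the downstream analysis uses, so the tail shape is a modeling
convenience); OTX2 peak offsets from a two-component normal mixture
(means −250 and +650 bp, sds 150 and 200 bp, weights ½/½) or uniformly
over ±2000 bp when configured; a MYC flag with class-conditional
probabilities 0.638 (multiple), 0.487 (single) and, for OTX2-free
promoters, the value solved from the law of total probability so the
MYC marginal hits 0.515 (an infeasible marginal raises before any
output); one MYC peak offset from N(0, 200 bp), or coupled to a
randomly chosen OTX2 peak plus N(0, 150 bp) noise for power studies;
expression from per-class normal laws (log2 means: unbound 5.0,
MYC-only 6.0, single−MYC 5.8, single+MYC 6.3, multi−MYC 6.0, multi+MYC
7.5; common sd 1.0).

The mixture sds are tight enough that the binned percent-bound profile
localizes each mode to within one 50 bp bin at 10,000 bound promoters
in ≈95% of replicates; with substantially wider components the density
curvature at the mode falls below the binomial bin noise and the
argmax wanders, so mode recovery at one-bin resolution is a genuine
constraint on the offset spread, not just a convenience.

Layout: one synthetic chromosome per 1,000 promoters; TSSs every 10 kb
(so profiled windows never overlap) with random strands. Probe tracks
sample every 100 bp across each promoter window; values are Gaussian
bumps at peak centers (amplitude = the peak's log2 signal, sd =
peak width/4) plus N(0, 0.3) noise. Sequence is uniform-random ACGT
with: TAATCC-family motifs planted as a piecewise-constant Poisson
process (rate 1/500 bp, ×0.2 within ±500 bp of the TSS), E-boxes as a
uniform 1/1000 bp process plus a triangular bump peaking at the TSS
(5× at the center, ±250 bp) so the enrichment maximum is identifiable
at bin resolution, and on average one 300 bp lowercase (soft-masked)
Alu-like insertion per promoter outside the ±500 bp core, each carrying
two lowercase TAATCC copies. Random background sequence itself contains
any fixed hexamer in ~2.2% of 50 bp bins (both strands), which is the
floor under all planted densities. `SyntheticConfig.motif_rate` exposes
the configured placement law as the oracle for density tests.

`generate_fixture_from_counts` is fully deterministic: it realizes an
exact contingency table (total / single / multiple / MYC margins and
joint cells), planting one OTX2 peak at −250 bp for single promoters,
two (−250 and +650) for multiple, and a TSS-centered MYC peak where
flagged, after validating the table's internal consistency.

What the generator does **not** emulate: probe-level array noise beyond
additive Gaussian, correlated probe effects, width variation of peaks,
linkage between the planted sequence motifs and where peaks are placed,
overlapping promoter windows (unless TSSs are planted closely on
purpose), and real repeat taxonomy. Passing tests therefore demonstrate
the correctness and power of the *analysis machinery* under the stated
statistical structure, not fidelity to any particular array platform.

## Problem sizes used in the automated checks

The test suite and acceptance script size their simulations to the
analysis at hand: full 25,064-promoter datasets where marginal fractions
or mode locations are measured; 10,000 bound promoters × 20 replicates
for mode-recovery rates; 100 replicates of ~300 promoters for the
distance-null calibration and the null-uniformity of class-expression
p-values; 5,000 promoters for the coupled-offset power check; 2,000
promoters with sequence for motif-density recovery. The exhaustive
hypergeometric validation covers every (N, K, n, k) with N ≤ 60 against
rational arithmetic.

## Known limitations

- The randomization null fixes MYC peaks; a bivariate null (both
  factors redrawn) would be needed to ask symmetric questions.
- The Fisher tables treat the scaled null as data, understating null
  uncertainty when R is small; this mirrors the pooled-randomization
  design rather than a full permutation test.
- The k-mer score is a plain frequency-ratio statistic; it is not a
  position-weight model and makes no multiple-testing correction, so
  round-by-round scores are descriptive.
- Motif scans are exact-match only; degenerate alphabets (e.g. the full
  CANNTG E-box family) are supported only by enumerating the expansion
  into the motif set.
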