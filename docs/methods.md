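# Methods

`hsmap` reconstructs sex-specific genetic maps for the laboratory rat from
heterogeneous-stock (HS) pedigree genotypes, cleans them against the physical
assembly, turns them into community resources (per-kb cM tables, marker
annotation, chromosome summaries), and quantifies how marker re-positioning
moves QTL in F2 interval-mapping scans.  Because the real HS genotypes are an
external resource, the package ships a first-class cohort simulator whose
ground truth is the published chromosome-level map itself; every downstream
stage is validated by parameter recovery against that truth.

## The synthetic HS cohort

An HS colony descends from eight inbred founder strains.  The simulator
represents each strain as a single homozygous haplotype over a biallelic
marker panel (default 85% of markers polymorphic among strains, with the
derived-allele count uniform on 1..7; the remainder monomorphic so that QC
has something to remove).  Families are three-generation: four inbred
grandparents (strains drawn without replacement), one sire and one dam bred
from them — heterozygous mosaics of two strains — and a sibship of
final-generation offspring.  With 65 families and ~6.7 offspring each, the
cohort contributes 870 informative meioses (two per genotyped final-generation
offspring), matching the mapping resource the package models.

Gametes recombine under a sex-specific Poisson process on the cM scale
(crossover count per chromosome ~ Poisson(L/100); positions uniform in cM and
mapped to bp through the inverse of the truth map).  This is deliberately the
exact generative inverse of the Haldane mapping function used in estimation,
so map estimation is asymptotically unbiased by construction.  No crossover
interference and no obligate chiasma are imposed by default (a stationary
gamma-renewal interference model is available behind a flag); these are known
realism gaps — real rodent meioses show positive interference — so passing
recovery tests demonstrate correctness of the estimation machinery, not that
the error model matches real arrays.  The X chromosome is simulated as an
autosome with its published male/female lengths.

Genotype corruption: symmetric single-allele swaps at a per-call error rate
(default 0.2%), missing calls (default 2%), and a fraction of markers
(default 2%) with a strongly inflated per-call error rate (5%) so that their
cohort Mendelian-error rate exceeds the 2% QC threshold.  A separate operation
displaces a minority of markers' physical positions by at least a set shift
(default ≥20 Mb) to emulate assembly errors ("errant" markers); the genetic
data keyed by marker id are unchanged, and the displaced ids are returned as
truth for cleaning tests.

## Genotype QC

Three stages, in order: (1) monomorphic removal — markers with fewer than two
alleles among non-missing calls are dropped (all-missing markers count as
monomorphic); (2) Mendelian-error filtering — per marker, the error rate is
trio-incompatible offspring calls over complete trios, and markers with rate
strictly above 2% are dropped (a marker with no complete trio is retained and
flagged); (3) window thinning — per 10-kb window anchored at bp 1
(half-open on the right), the lowest-bp marker with MAF strictly above 0.05
is retained.  MAF is computed over all genotyped individuals, founders
included.  All three filters are idempotent.

## Map estimation

Marker order is taken from physical positions and never re-estimated.

**Parental calling.** Missing parental genotypes are imputed only when
logically forced by the non-missing genotypes of the parent's own parents,
its mate and their offspring; markers admitting no compatible configuration
are flagged as contradictions and left missing.

**Segregation distortion.** Pooled offspring genotype counts are tested per
marker against Mendelian expectations given parental dosages (Pearson
chi-square; each parent transmits its B allele with probability dosage/2);
markers with p < 0.001 are removed.  The threshold mirrors the documented
default tolerance of the linkage-mapping software this stage replaces and is
configurable.

**Phasing.** For each heterozygous parent and chromosome, transmissions are
resolved per offspring where determinate (offspring homozygous, or offspring
heterozygous with a homozygous mate), and the parent's phase is chosen to
minimise recombination events.  Chromosomes with at most 12 heterozygous
markers are phased exhaustively; larger ones by a sequential chain: each
column's orientation is the majority vote of the meioses resolved there,
compared against their most recent *stable* origin (one whose last two phased
origins agree — a meiosis whose origin just changed abstains, because a
one-marker-old change is equally likely a miscall or a fresh crossover).
Columns where every resolved meiosis received the same allele while their
current origins split are logically impossible for a genuine heterozygous
marker and are voided as pseudo-heterozygous miscalls.  A cleanup pass then
removes residual phase switches (junctions where most spanning meioses would
otherwise all "recombine" at once, plus bounded mis-phased regions found by
trial flips).  Parents heterozygous at under 1% of a chromosome's markers are
treated as uninformative there: their rare heterozygous calls are almost
surely genotyping errors (e.g., in inbred founders), and their long
pseudo-spans would otherwise dilute coverage.

**Error tolerance.** Origin runs supported by fewer than 3 resolved markers
are voided as presumptive genotyping errors.  At a 0.2% per-call error rate
over ~40,000 markers, unfiltered two-point counting would admit roughly as
many spurious crossovers as true ones; the support filter removes them at the
cost of hiding true close double crossovers, which is corrected below.

**Interval estimation.** For each transmitting-parent sex, every meiosis
informs all adjacent-marker intervals between its consecutive resolved
markers (the span), and a recombinant span contributes its event
fractionally to those intervals in proportion to bp length.  The estimate is
r = k/n per interval, converted to cM by Haldane's function (Kosambi
selectable); intervals with no informative meiosis are flagged and assigned
0 cM, to be bridged by the spline.  Conditioning on parental heterozygosity
is independent of the crossover process, so r̂ is unbiased per interval, and
the genome total is an event-count estimator whose sampling error is the
Poisson floor of the meiosis count (~1.1–1.2% SD per sex at 870 meioses —
no estimator can beat this, which is why the recovery tolerance of 2.5% per
seed is met in *most*, not all, replicates).  Two small Poisson-model
corrections, computed from the first-pass map, scale each chromosome:
(a) span parity — even crossover counts inside a span are invisible; and
(b) support-filter losses — crossover pairs whose middle run has fewer than
3 resolved markers are voided (pairs hidden inside a single span are already
covered by (a); events voided in terminal gaps take their coverage with them
and need no correction).  Both corrections are ~1–2%.

**Per-marker placement diagnostic.** For each marker, the count of meioses
whose origin there disagrees with two agreeing resolved flanks is compared
against the genome-wide background (robustly estimated isolated-mismatch
rate) by a Poisson tail test (α = 10⁻³, minimum 2 mismatches).  Flagged
markers receive a Haldane-scale offset (their mismatch rate transformed to
cM) — a physically displaced marker's mismatch rate approaches the
recombination fraction of its true-to-reported separation, so the offset
estimates the displacement in map units.  The diagnostic pools meioses of
both sexes: displacement is a property of the assembly, not of sex, and
per-sex offsets at ~435 meioses would carry ~0.5 cM of noise against the
fixed 1 cM removal threshold.

Estimation is two-pass: markers flagged by the diagnostic are excluded from
a second-pass backbone (the cohort is re-phased without them, since errant
markers also corrupt their neighbours' phase) and re-enter the final map at
their backbone-interpolated cM plus their offset.  The final map carries
cumulative cM per marker for male, female and averaged tracks (averaged =
arithmetic mean of the sex tracks, which is how the published table's
averaged column is formed), each chromosome starting at 0.

**Replicates.** Optional family-level bootstrap replicates are averaged per
marker and re-monotonised isotonically (off by default).

## Map cleaning

Stage one fits a LOESS curve (local linear, tricube weights, span 0.1 of the
chromosome's markers) of observed genetic position — cumulative cM plus
placement offset — on bp, per chromosome and per sex track, and removes
markers with absolute residual strictly above 1 cM.  A marker removed in
either sex track is removed from all tracks.  Unlike a plain one-pass LOESS,
gross outliers are excluded and the fit re-run (up to twice): with ~5% of
markers displaced by ≥20 Mb (~13 cM), a non-robust fit is dragged ~0.5–0.7 cM
toward the outliers, pushing clean neighbours over the fixed threshold.
Chromosomes with fewer than 10 markers are left unfiltered with a warning.

Stage two fits a shape-preserving monotone piecewise cubic (PCHIP,
Fritsch–Carlson) through the retained anchors per chromosome and track —
bp ties collapsed to mean cM, residual non-monotonicity removed by isotonic
projection first — giving a non-decreasing bp→cM model that reproduces every
anchor exactly.  Its derivative (scaled to cM/Mb) is the local recombination
rate; beyond the terminal anchors the model extrapolates at the terminal
slope, clamped at cM ≥ 0, and flags such queries.  A smoothing spline was
deliberately not used: exact anchor reproduction and guaranteed monotonicity
are the contract here.

## Resources and summaries

The fitted model emits cM values (three tracks) at every kilobase of the
physical assembly, annotates arbitrary marker lists (markers with no
position, an unknown chromosome, or multiple listed positions are flagged
`unmapped` and given no cM; out-of-range positions are extrapolated and
flagged), and produces chromosome summaries: marker count, cM per track
(1 decimal), physical Mb, and rate = averaged cM / Mb (2 decimals).  Two
genome-wide rate conventions are reported: the **unweighted mean of
per-chromosome rates** — the headline convention, which reproduces the
published 0.66 (revised) and 0.65 (historical) cM/Mb figures — and the
weighted ratio of totals (1,708/2,619 = 0.65 for the revised map).  Note a
quirk of the published summary table: its revised-map physical-size total
(2,619 Mb) equals the chromosome column summed *without* chrX (the cM and
marker totals include chrX, as does the historical Mb total); genome-level
reference figures therefore quote the printed totals row as printed.

## QTL reanalysis machinery

F2 crosses travel in the comma-separated cross format (marker names /
chromosomes / cM header rows, then one row per individual with phenotypes and
AA/AB/BB/− genotype codes).  Unobserved genotypes on the scan grid (union of
marker positions and a 2-cM lattice) are sampled by forward-filtering
backward-sampling under a Markov model along the cM map with Haldane
recombination probabilities and an error-free emission model (observed marker
genotypes are reproduced exactly in every imputation; the per-call error rate
of the hidden-genotype model is fixed at 0).  At each grid position,
LOD = (n/2)·log10(RSS0/RSS1) compares covariates-only to covariates +
additive + dominance terms (optionally covariate-by-genotype interactions,
covering additive and interactive model specifications generically);
imputations combine as log10 of the mean of 10^LOD.  Genome-wide thresholds
come from permuting the phenotype (default 1,000 permutations; significant =
0.05, suggestive = 0.63 genome-wide levels).  The Bayes credible interval is
the smallest consecutive grid window containing the peak whose normalised
10^LOD mass reaches the coverage (ties broken to the lowest cM and leftmost
window).  Old-map vs new-map comparisons match QTL by (phenotype, model,
chromosome); the shift |new − old| is defined where a QTL is detected under
both maps and flagged when strictly greater than 10 cM.  The comparison
denominator counts QTL detected under both maps, which is how the published
9-of-32 figure arises from a 33-row table with one undetected entry.
The named models of the original behavioural study are defined in that
study's own report, not reproduced here; the scan accepts a generic covariate
specification instead.

## Problem sizes used by the tests and the acceptance script

Parameter recovery simulates the full 21-chromosome rat genome at ~2,000
markers per chromosome (~42,000 markers), 65 families / 870 meioses, 0.2%
call errors, 2% missingness; the test suite evaluates 20 replicate seeds
(tolerance 2.5% per total, required in ≥95% of seeds) and the acceptance
script reports means over 8 replicate seeds.  Cleaning efficacy uses one such
cohort with 5% of markers displaced ≥20 Mb.  Bayes-interval coverage uses 200
planted-QTL F2 crosses (n = 250, one 100-cM chromosome, markers every 10 cM,
additive effect 0.5 SD, 16 imputations).  These sizes are the package's
standard validation settings; the simulator and study helpers accept larger
ones.

## Known limitations

- No crossover interference by default; estimation assumes Haldane
  throughout, consistently with the simulator.
- Two-point estimation with support filtering loses a small, corrected-for
  fraction of tightly spaced double crossovers; a multipoint HMM would
  recover them but is out of scope.
- Near chromosome ends, coverage comes mostly from meioses for which the
  region lies in their own terminal span, where voided terminal runs
  condition coverage on the absence of crossovers; the first and last few
  resolved-marker spacings of each chromosome are therefore slightly
  under-estimated.  The effect scales with marker spacing: at study density
  (~0.1 cM spacing) it is a fraction of a percent of a chromosome's length,
  but it is visible in coarse small-demo runs.
- The placement diagnostic detects displacement magnitude, not direction;
  errant markers are removed, never re-positioned.
- The male X-chromosome track is estimated like any autosome when the
  simulator runs the X as an autosome; a hemizygous-male X mode restricts
  information to female meioses and leaves the male X track empty.
- The QTL scan is single-locus; no multiple-QTL or epistasis models.
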