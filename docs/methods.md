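# Methods

## Scope and model of the data

`ascopy` operates entirely in the post-segmentation world: each tumor is an
ordered set of genomic segments with integer major/minor allele copy
numbers (a ≥ b ≥ 0), as produced by allele-specific callers such as ASCAT.
Raw array preprocessing, segmentation and purity/ploidy deconvolution are
upstream of this package and are never re-estimated here; when a caller
supplies per-sample ploidy or aberrant cell fraction, those values are
trusted (the supplied ploidy always wins over the internal estimate, which
is logged for comparison).  Internal coordinates are 1-based inclusive;
BED input/output converts at the boundary.  Segments need not tile the
genome: uncovered bases are missing data, never imputed as diploid.

The packaged genome layout is an hg19-style arm table: 24 chromosomes × 2
arms minus the five acrocentric p-arms (13p, 14p, 15p, 21p, 22p) whose
short arms carry no SNP-array calls, i.e. 43 arms.  Users can substitute
any layout via an arm TSV or a UCSC cytoband file.  No genome build is
forced on the data; the default layout simply has to match the coordinates
of the supplied segments.

## Ploidy and aberration calls

Ploidy is the length-weighted median of segment total copy numbers: the
smallest value v such that segments with c ≤ v cover at least half of the
profiled genome.  The lower-median tie-break keeps the estimate
deterministic and integer-valued on integer input.  A segment is called a
gain when c > P + δ, a loss when c < P − δ, and normal otherwise.

Two δ defaults are used deliberately.  Recurrence analysis uses δ = 0, the
strict reading of "exceeding the ploidy": with a non-integer ploidy this
leaves no normal class, which is the intended behaviour for frequency
tracks (every base is either above or below a fractional genome average).
The cis-expression analysis, by contrast, *requires* a normal class to
anchor its two t-tests, so gene-level grouping there uses δ = 0.5 — half a
copy, the natural resolution of integer copy states around a continuous
ploidy.  Both are exposed as flags.

## The eight complexity indices

A profile restricted to region R is compressed into eight non-negative,
length-normalised scores (formulas in the README and in
`ascopy/complexity.py`).  The design constraints were: every score weighs
both the magnitude and the width of an aberration; the first six scores use
total copy numbers and the last two the allele-specific values; *loh*
counts only events where one allele is completely lost and *asym* only
events where both are retained; and the ploidy-deviation score decomposes
exactly into its gain and loss parts (J4 = J5 + J6), which the tests
assert everywhere.

Numerical and structural choices:

- **Width cap w₀ (default 3 Mb).** *steep* and *curv* target focal complex
  events.  Weighting a breakpoint by the narrower flank capped at w₀ lets a
  narrow shift count fully while preventing two long flat arms from
  dominating a single transition.  3 Mb is a conventional focal scale;
  the cap is configurable in `ScoreConfig`.
- **Merging.** Adjacent segments with identical (a, b) are merged before
  scoring, so breakpoint terms reflect true copy transitions and all eight
  scores are invariant under splitting a segment into identical halves.
- **Adjacency.** Consecutive segments of one chromosome are adjacent even
  across a small coverage gap (segmentation output rarely tiles
  perfectly); chromosome boundaries never form breakpoints.
- **Degenerate regions.** A region with zero covered bases yields missing
  (NaN) scores, not zeros — an unobserved arm is not a quiet arm.
- **Homozygous deletions** (c = 0) contribute to *loss* but not to *loh*:
  nothing is retained, so there is no "retained allele" asymmetry to score.
- **Regional median** m uses the same lower-median tie rule as ploidy.
- **Scale invariance.** J1 and J4–J8 are exactly invariant under uniform
  rescaling of all lengths.  J2/J3 are invariant only when w₀ is co-scaled,
  because the cap is an absolute width; the property tests check both
  statements separately.

The eight scores are emitted raw, without variance stabilisation or rank
transformation; any display scaling is left to the user.

## Recurrence

All samples' breakpoints partition each chromosome into atomic intervals.
Per interval, gain/loss frequencies are computed over *covering* samples
(the per-interval n is reported) rather than the whole cohort, so
unprofiled regions do not dilute the signal.  Recurrent regions are maximal
runs of abutting intervals with frequency ≥ p (inclusive; default
p = 0.30); no minimum width is imposed, and single-interval regions are
retained.  Annotation attaches genes and cytobands overlapping a region by
at least one base.

## Group comparison

Welch's unequal-variance t-test is the default two-sample test — group
sizes in stratified cohorts are routinely unbalanced — switching to the
Wilcoxon rank-sum test when a Shapiro-Wilk test rejects normality at
α = 0.01 in either group ("strong" deviation; constant groups are routed
to the rank test directly).  Bonferroni correction is applied over the
family of all scores tested in a mode: m = 8 genome-wide, m = 8 × arms
arm-wise.  −log10 raw P values are emitted for display; the significance
criterion is always the adjusted P at α = 0.05.

Covariate adjustment (ploidy, aberrant cell fraction) is ordinary
least-squares residualization with an intercept, applied per score column
before testing.  The choice of linear residualization is this package's
own: it is transparent, preserves the two-group test machinery, and its
null validity is checked by simulation in the test suite.  Samples missing
a covariate are dropped with a log message; constant covariates are dropped
with a warning (the fit then reduces to centering).

## Cis-expression integration

Gene position is reduced to its midpoint for segment matching — expression
probes can span breakpoints, and the midpoint rule is deterministic and
symmetric.  The raw total copy number of the covering segment (not a
log-ratio) is paired with log2 expression.  A gene is cis when Pearson
r > 0.4 and at least one of two Welch tests (loss vs normal, normal vs
gain; groups from δ = 0.5 calls; each arm needs ≥ 3 samples) has P < 0.05.
No multiplicity correction is applied at this stage — the criterion is
deliberately liberal, with the correlation threshold doing the heavy
lifting; under an expression-independent null the compound rule calls
≤ 2% of genes at n = 100 (checked by simulation).  The smaller P is
rescaled to Z = −F⁻¹(P) for display only.  Genes with fewer than 10
matched pairs, or with constant copy number across samples, are reported
but never flagged cis.

Gene-set enrichment is a one-sided Fisher exact test per set on the
(in-set × cis) 2×2 table over the tested-gene universe, BH-corrected
across sets.  GMT input makes this knowledge-base agnostic.

## Synthetic cohorts

The generator emulates caller *output*, not arrays: integer allele-specific
segments, a stamped continuous ploidy (the length-weighted mean total copy
number of the emitted profile, mirroring how callers report ploidy) and a
purity value drawn from a clipped normal (mean 0.533, SD 0.15, range
0.21–1).  Per sample, a ploidy target is drawn from a mixture — defaults
2.0 / 3.5 / 5.5, reflecting the near-diploid, near-tetraploid-minus and
high-ploidy modes of real tumor cohorts.  The baseline genome assigns every
arm the integer floor of the target, with a Bernoulli-chosen fraction of
arms (the target's fractional part) getting one extra copy; this lands the
weighted-mean ploidy on the target (tested to ±0.25) while keeping all
states integer.  A pure sequence of whole-genome doublings was rejected as
the baseline mechanism because it can only reach ploidy 2, 4, 8 and could
never produce the 3.5 / 5.5 modes.

Events are layered on with Poisson counts per class and uniform placement
within arms: whole-arm ±1 on one allele, focal ±1 (length 0.1–3 Mb),
focal-complex clusters of k alternating ±1 sub-segments (k ∈ [3, 8]),
regional LOH (minor allele → 0; copy-neutral, total preserved, half the
time) and allelic asymmetry (major +1 where the minor is retained).
Overlapping events compose sequentially with alleles floored at zero.
Every event is recorded in the truth table, and emitted tables round-trip
through the package's own reader.

Matched expression is `mu_g + beta_g * (c_gs − P_s) + N(0, sd)` with
`beta_g = beta` for a random cis fraction of genes and 0 otherwise,
`mu_g ~ N(7, 1)` on the log2 scale.  Defaults (beta = 1, sd = 0.5,
cis fraction 0.2) give planted cis genes a population correlation near 0.8
when copy variance at a locus is about 0.5.

What the generator does **not** model: subclonality and non-integer mixed
states, purity-driven signal attenuation, wavy baselines and segmentation
error, gene-length and GC effects on expression, trans effects, and
linkage between event types.  Passing tests on these cohorts therefore
demonstrate the pipeline's correctness and statistical calibration under
clean caller-like input, not robustness to segmentation artifacts.

## Problem sizes and runtime choices

The test and acceptance workloads are sized for a laptop-class single CPU:
oracle-parity checks use 50 random two-chromosome genomes of ≤ 10⁴ bases
(small enough for literal per-base expansion); cis recovery uses 10
replicates of 100 samples × 1,000 genes (200 planted cis genes at
population r ≈ 0.8); comparison validity uses 1,000 null replicates at
n = 30 per group.  These sizes give stable estimates (binomial SE on the
family-wise error at 1,000 replicates is ≈ 0.7 percentage points) without
long runtimes.

## Known limitations

- The eight indices realize the verbal definitions above; other
  formalisations of "steepness" or "oscillation" are possible, and no
  attempt is made to numerically match any unpublished implementation.
- Frequency tracks treat each sample's calls as fixed labels; no
  uncertainty in the underlying segmentation is propagated.
- Linear covariate adjustment can under-correct when score–covariate
  relationships are strongly nonlinear.
- Pearson correlation in the cis criterion is sensitive to copy number
  outliers (high amplifications); the compound rule mitigates but does not
  remove this.
- The generator's uniform event placement has no hotspot structure, so
  recurrent regions in simulated cohorts arise only from event density,
  not from positional selection.
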