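# Methods

## Coverage model and normalization

The unit of analysis is the 1 Mb bin. Alignments are assigned to the
half-open bin containing their start position — each retained read counts
exactly once — after filtering to primary, properly paired reads with
MAPQ ≥ 30. `total_reads` is the retained count, so normalization and
filtering act on the same read universe.

Two-step normalization divides each bin by the line's total and then by the
wild-type line's corresponding value. Because exome capture gives each bin
a probe-dependent efficiency shared between lines sequenced with the same
probe set, the efficiency cancels in the ratio; the paired-simulation test
verifies this cancellation directly. Bins where the wild type has zero
reads (no probes) are masked with NaN rather than set to a number: a
division by zero is undefined, and a probe-free gap must be able to sit
inside a deletion without either splitting it or extending it. Masked bins
are therefore neutral everywhere downstream — excluded from moving-average
windows and counted toward neither the low nor the high run of the caller.

Chromosomes assembled as two "parts" scaffolds are lifted to full
coordinates by shifting part-2 positions by part-1's length. Part 1's short
terminal bin is retained, so full-coordinate bins on the second half are
offset from 1 Mb multiples — this is why several published deletion
boundaries end in values like …555092. The lift is a coordinate bijection;
the inverse lift restores parts coordinates exactly.

The window-4 moving average exists for plotting only. Calling always runs
on raw bin values; smoothing a profile before applying run rules would
change the effective thresholds.

## Deletion calling

A deletion opens at the first bin of a run of ≥ `min_low_run` (default 4)
adjacent bins with normalized value ≤ `low_fraction` (default 0.1), and
closes at the last low bin preceding a run of ≥ `min_high_run_to_terminate`
(default 4) adjacent high bins, or the chromosome end. Two consequences of
this rule pair are deliberate:

- interior high runs shorter than the termination run are absorbed into a
  single call (the deletion is not "finished" until four high bins occur);
- the reported end is the last *low* bin, so calls are low-coverage extents,
  not gaps between high regions.

The production scanner is a single-pass state machine; the test suite keeps
an independent run-length-segment implementation and checks equivalence
exhaustively on every {0,1} profile of length ≤ 20 (about 2 million
profiles), plus randomized profiles with intermediate values and masks.

Calls overlapping between independent mutant lines on the same chromosome
are flagged `background_polymorphism_suspect`, never removed: independent
irradiation events should not coincide, and a shared drop in coverage is
characteristic of a polymorphism between the background variety and the
reference assembly that misaligns reads in every line. The analyst decides
what to do with flagged calls.

Border refinement operationalizes manual inspection of alignments at call
borders as a gene-coverage threshold scan: among gene models with wild-type
capture coverage, the refined interval spans the contiguous run of genes
whose own normalized mutant coverage is ≤ `low_fraction`, intersecting the
bin-resolution call; the nearest covered genes on either side are reported
as flanks. The same threshold is reused deliberately — the choice of a
numeric rule here was open, and one shared, documented threshold keeps the
behavior reproducible. A consequence worth stating: the refined interval
is bounded by genes, so it cannot reach into gene-free margins of the true
deletion; where annotation is sparse at a border, refined coordinates
under- or over-shoot accordingly (an effect the original analysis also
reported). If no low-coverage gene intersects the call, the bin-resolution
call is returned unchanged.

Gene content is ≥ 1 bp overlap on half-open intervals; homoeologue
intersection pairs genes greedily in coordinate order with each gene in at
most one pair, which makes the reported pair count well defined when the
homoeology relation is not one-to-one.

All coordinates are 0-based half-open everywhere internally; GFF3 (1-based
closed) is converted at the file boundary. This makes size = end − start
exact for every reported interval.

## Marker genotyping

Dominant PCR assays cannot distinguish heterozygotes from homozygous wild
type, so the only identifiable state is homozygous deletion. An absent
product is a putative deletion; a faint band is treated the same but
propagated as low-confidence evidence ("FAINT" and "Faint" are one call).
Extent classification assumes one contiguous deletion per arm and uses the
panel order, not the observation order; the classes are: none deleted, all
deleted, all-but-anchor deleted (distal deletion stopping short of the
anchor locus), anchor only, any other contiguous block (interstitial), and
`inconsistent` when contiguity is violated — violations must surface rather
than be forced into a class.

For the multiplex marker the A genome contributes two products, so the A
genome is called deleted only when both are absent or "very small". What
counts as a peak "very small relative to the others" is inherently
qualitative; the implemented default is height < 0.2 × median of the
nonzero peaks, configurable.

## Segregation

Genotype classes are defined over per-locus homozygous-deletion status
(the only status dominant markers resolve); for `n` loci the partition has
2^n classes with P(homozygous at locus i) = p_i² and independent loci
multiplying. The bias test reports the chi-square statistic with
df = classes − 1, switching the p-value to an exact binomial tail when any
expected count is below 5, and *always* reports the exact one-sided tail
for a focal class (default: the smallest-expectation class). The rationale:
with 457 plants and an expected 1/16, the chi-square approximation is
formally fine, but the scientific question — is the double-mutant class
depleted? — is a single-class question that the exact tail answers
directly.

## Granule morphometry

The measurement chain is binarize → watershed → measure → two-pass count.
Binarization defaults to Otsu's global threshold with granules darker than
background (iodine-stained starch in bright field); a fixed threshold and
an inversion flag are available. Touching granules are split by a
watershed on the negative Euclidean distance transform, with markers at
local maxima of the lightly smoothed (σ = 1 px) distance map separated by
≥ 4 px; the smoothing suppresses spurious maxima from boundary pixelation
without merging the two maxima of moderately overlapping discs.
Border-touching particles are excluded by default (partial granules bias
areas low).

The class cutoffs are the circle areas of the diameter limits: π(1/2)² =
0.785 µm² and π(10/2)² = 78.5 µm² at the printed precision, both bounds
inclusive (the convention of the particle-analysis tool the workflow
mirrors; stated here because inclusivity is otherwise ambiguous).
Per image, pct_small = 100 × count(area in [0.785, 78.5]) / count(area ≥
0.785); the sample value is the unweighted mean over images. Per-image
weighting was an open choice — slides pool two starch preparations — and
unweighted per-image averaging is the implemented default.

Swelling power is swollen-pellet weight / dry weight, dimensionless.

## Synthetic data: what it emulates, and what it does not

The coverage generator draws one lognormal capture-efficiency factor per
bin (σ = 0.3), shared between lines, with Poisson counts around mean 100
reads/bin at efficiency 1 and a residual fraction 0.02 retained inside
planted deletions — deletions in real capture data show trace off-target
signal rather than zero, and a nonzero residual keeps the ≤ 0.1 threshold
meaningfully exercised. Lines are simulated homozygous, as the sequenced
lines were (heterozygous depth ≈ 0.5 is available via the residual
parameter but unused by default). The packaged line layouts transcribe the
published bin-resolution deletion tables; chromosome lengths are the
published assembly's approximate lengths (exact where a deletion ends at a
chromosome end), and part-1 lengths are chosen so the lifted grid
reproduces the printed coordinates. Not emulated: mappability structure,
GC bias, paired-end fragment effects, and real probe layouts — so passing
tests demonstrate the inference logic under the stated noise model, not
robustness to every artifact of real capture data.

The gene-model generator places non-overlapping 3 kb genes uniformly (per
Mb density), pairs a stated fraction across two designated chromosomes at
proportionally scaled positions, and emits truth coverage of 1 minus the
deleted fraction of each gene. The marker generator deletes exactly the
markers whose positions fall in planted deletions, reporting a configurable
fraction as faint. The granule generator renders filled discs with
lognormal diameters (medians 5.2 µm and 18.4 µm, σ = 0.25, giving mean
class areas near 24 and 300 µm², the measured control values), exact class
counts (n_small = round(n × f), so recovery error measures the pipeline,
not binomial sampling), limited controlled overlap, optical blur (σ = 0.8
px) and Gaussian pixel noise at 0.5 µm/px; it does not model uneven
illumination, out-of-focus granules, or debris.

## Problem sizes and numerical choices

Default simulations use the full multi-chromosome line layouts (~2,600 and
~3,700 bins), 50-replicate recovery checks on a compact one-chromosome
genome, and granule recovery on three 250-granule images per composition —
sizes chosen so the whole suite runs in well under a minute per module on a
single CPU while keeping sampling error far inside the tested tolerances.
Ties and degenerate inputs: empty profiles yield empty call lists (not
errors); a blank image yields an empty mask with a notice; images with no
qualifying particles are excluded from sample means with a notice; all
random draws flow from explicit integer seeds via NumPy's default
generator, making every generator bit-reproducible.

## Known limitations

Real-annotation quantities (refined border coordinates, per-deletion gene
counts, shared-homoeologue totals) depend on the exact reference annotation
and are validated here only in the property sense on synthetic annotation.
The caller's resolution is one bin: breakpoints inside a bin are invisible,
and deletions shorter than `min_low_run` bins are out of scope by design.
The watershed splits moderately overlapping convex particles; heavily
clumped granules (overlap fractions well above ~0.2) will undercount.
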