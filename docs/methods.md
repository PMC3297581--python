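# Methods

This note documents the models, conventions and design decisions behind
`tfcoreg`, in the order the pipeline runs them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and peak filtering

All intervals are 0-based half-open (BED convention). A peak is significant
when its multiple-testing-corrected q-value is **at or below** the threshold
(default 0.001); the boundary is inclusive and covered by a test. Filtering
preserves input order and never modifies rows.

## Peak-to-gene assignment

A peak is assigned to gene *g* when it overlaps (≥ 1 bp intersection) the
window `[tx_start − U, tx_end)` for `+` genes or `[tx_start, tx_end + U)`
for `−` genes, with `U` = 3000 bp by default. The TSS of a `−`-strand gene
is `tx_end` and its upstream window extends rightward — the standard strand
convention, stated explicitly because annotation sources are often silent
about it. Design choices:

* **Overlap, not summit distance.** The data model carries no summits;
  "present within" a region is an interval statement.
* **Multi-gene hits are kept.** A peak in a bidirectional promoter is a
  target of both genes; collapsing to the nearest gene would silently
  shrink target sets.
* **"inside" wins over "upstream"** when a peak touches both the upstream
  window and the gene body: the assignment table records the more specific
  relation. The choice affects only the relation label, never membership.
* Peaks on chromosomes absent from the annotation raise a warning and count
  as unassigned (they stay in the denominator of `fraction_assigned`).

Growing `U` can only grow the target set (monotonicity, tested), and the
assignment is invariant under input permutation and coordinate mirroring.

## Co-binding statistics

**Overlap significance.** With universe size N, target sets of sizes K and
n, and intersection k, the tail P(X ≥ k) for X ~ Hypergeom(N, K, n) is
evaluated through `scipy.stats.hypergeom.logsf`. The log-space value is
always reported alongside the probability because realistic inputs push the
tail far below double-precision underflow (the acceptance suite exercises a
case near 10⁻¹⁰⁷⁴, where the probability prints as 0.0 but the log10 value
stays finite and exact percentages are unaffected). Published joint-target
analyses sometimes print tail probabilities (e.g. ~10⁻⁵⁶) that are many
orders of magnitude larger than the standard tail computed from the same
printed set sizes; the parameters behind such numbers are typically
unstated, so this package implements only the standard tail and reports
both scales rather than attempting to reconcile any particular printed
value.

**Percent truncation.** Reported whole-number percentages truncate toward
zero (3915/5393 = 72.59 → 72) because that is how the printed tables such
summaries mirror are rounded; the raw percentages are always emitted too.

**Proximity.** The distance from an A-peak to a B-peak is 0 when the
intervals overlap or touch, else the edge gap; per A-peak the minimum over
same-chromosome B-peaks is taken (an O((n+m) log m) sweep with a
prefix-maximum of interval ends, verified against an O(n·m) brute force).
A-peaks on chromosomes with no B-peak get distance ∞: excluded from the
windowed numerator, kept in the denominator. The window comparison is
inclusive (≤ 500 bp), consistent with "within".

## Motif model

A PWM stores strictly positive per-position base probabilities (pseudocount
applied at construction) and a background distribution. Windows are scored
as Σᵢ log2(pᵢ(b)/bg(b)) on both strands; windows containing N are skipped
rather than imputed. The hit threshold defaults to **80 % of the motif's
maximum achievable score**. No universally accepted cutoff exists and
occurrence fractions are threshold-dependent, so every occurrence report
carries its threshold. Occurrence per factor is the non-duplicate union
over motif versions: a peak counts once however many versions or windows
match.

The bundled TCF7/RUNX1 matrices are synthetic consensus-derived
approximations built in-package (from the published consensus sites, e.g.
CTTTG(A/T)(A/T) for TCF/LEF and TGTGGT for the RUNX core) — they are
simulation and demo defaults, not database matrices.

**De novo discovery** fits a ZOOPS mixture: each sequence contains at most
one motif occurrence (prior γ), at a uniform position on a uniform strand,
against an i.i.d. uniform background. EM alternates site posteriors with
expected-count updates (pseudocount 0.25 per matrix cell); the likelihood is
monotone (tested) and the best of 10 seeded restarts is kept. EM over ZOOPS
was chosen over Gibbs sampling for exact determinism under a seed. The
model cannot distinguish a motif from its reverse complement, and like all
local-optimisation motif finders it may lock onto the planted register
shifted by ±1; comparisons therefore use the best sliding alignment rather
than position-locked identity.

**Motif comparison** slides one matrix (and its reverse complement) across
the other over all offsets with ≥ 4 aligned columns; similarity is the mean
Pearson correlation of aligned probability columns, ties broken by more
aligned columns, then smaller |offset|. Because a 4-column chance alignment
can reach near-perfect correlation, recovery checks pass `min_overlap`
commensurate with the motif width (e.g. 10 of 12).

## Expression quantification and differential calls

Multireads are allocated in a single pass: each group's count is split
across its candidate exons proportional to their unique-read counts, with a
uniform split when all candidates have zero unique reads. Mass is conserved
to 1e-9 (tested). A single pass is the minimal reading of the
unique-read-density allocation rule; no iterative re-estimation is applied.
RPKM uses the union of exon lengths, never the genomic span, and a gene of
zero exonic length is an error naming the gene. Whether "total reads"
counts all mapped reads or exonic reads only is left to the caller — the
`total_mapped_reads` argument is explicit, defaulting to the full library
in the pipeline.

Differential genes: condition means (arithmetic mean over replicates; the
combiner is a convention, stated here because 2+2 replicate designs leave
it open) must differ by ≥ `fold_threshold` (default 2.0) and both exceed
`min_rpkm` (default 2.0). The reported `fold_change` is the raw mean ratio
A/B so that direction and threshold remain mutually consistent; the
min-expression rule keeps DE-gene denominators away from zero. Both
thresholds are parameters because published analyses use 1.5-fold in some
displays and 2-fold in others.

Ranking for enrichment uses log2((mean_A + ε)/(mean_B + ε)) with
ε = 0.5 RPKM — small enough to preserve a > 100-fold dynamic range, large
enough to keep zero-expression genes finite. Ties break lexicographically
by gene id so ranked lists are fully deterministic. Z-scores (display only)
use log2(RPKM + 0.5), sample standard deviation (n − 1), and map
constant genes to all-zero rows.

## Pre-ranked enrichment

The running sum increments |score|^p / Σ_set|score|^p at set members
(p = 1, the weighted statistic) and decrements 1/(N − N_hits) at
non-members; it ends at exactly 0, and the ES is the extremum of the largest
magnitude (ties prefer the positive extremum). The leading edge is the set
members at or before a positive extremum (at or after a negative one).

The null is **gene-set permutation**: random same-size sets drawn from the
ranked universe, seeded. Phenotype permutation is degenerate with two
replicates per condition, which these designs often have, so set
permutation is the default and the permutation mode is recorded in output
metadata. The nominal p compares magnitudes against the whole null,
p = (1 + #{|ES_null| ≥ |ES|}) / (1 + n_perm): under the null the p of a
random set is uniform (measured 0.035–0.07 of random sets at p ≤ 0.05
across seeds in the acceptance suite), and the +1 correction reports a
zero-exceedance result as the bound p < 1/(n_perm + 1) rather than an
impossible 0 (the `p_is_upper_bound` flag, mirroring the "p near 0" display
convention). A sign-conditioned numerator over the full-permutation
denominator was rejected: it roughly doubles the null rate at any α because
it ranks within one tail while dividing by both. NES divides ES by the mean
magnitude of same-sign null scores (the standard normalisation), and FDR q
is the usual pooled NES-ratio estimator, clipped to [0, 1].

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of `(config, seed)`; seeds are split per
stage so outputs are byte-identical and order-independent. Planted events
are recorded in first-class truth tables — tests never re-infer ground
truth.

* **Genome/annotation.** i.i.d. background sequence at configurable GC
  (uniform by default — the simplest null for measuring scanner false-positive
  rates). Genes are placed constructively with ≥ 3 kb flanks, so placement
  either succeeds deterministically or fails with an explicit capacity
  error; exon structures are random but begin/end at the transcript bounds.
  One chromosome by default; more via repeated placement.
* **Peaks.** Exactly `round(cobind_fraction · n_peaks_a)` A-peaks receive a
  partner B-peak at an edge gap drawn from |Normal(0, sd)| — a half-normal
  kernel matches a "within 500 nt" windowed summary without asserting any
  binding mechanism. Remaining peaks are uniform. Decoy peaks with
  q > 0.001 are appended (5 % by default) so the significance filter does
  real work without disturbing planted counts. The default chromosome is
  2×10⁸ bp with 5000/7000 peaks: genome-scale peak density, and a background
  within-500-bp co-location rate (~3 %) small against the ±0.03 recovery
  tolerance.
* **Motifs.** An exact fraction of peaks receives one instance sampled from
  the PWM, at a uniform position and strand, rejection-sampled until it
  scores ≥ 80 % of the motif's maximum — so a scan at the planting
  threshold detects every planted site and recovered occurrence equals the
  planted rate plus the measured background false-positive rate. When two
  motifs are planted in the same peak the later one may overwrite part of
  the earlier (≈ 1 % of peaks at default widths), a small known loss.
* **Expression.** Baseline log2 expression is i.i.d. normal; up/down genes
  shift by ± the configured magnitude in condition A, with a configurable
  fraction of the up genes drawn from the designated target set; replicate
  noise is normal in log2 space and the back-transform keeps RPKM ≥ 0.
* **Read counts.** Per-exon unique counts are multinomial with weights
  (gene level × exon length); a configurable fraction of the library is
  emitted as multiread groups of 2–4 candidate exons. Unique plus multiread
  counts sum exactly to the requested library size.

What the generator does **not** emulate: read-level ChIP-seq signal,
fragment-length effects, peak calling, GC or mappability bias, correlated
gene expression, isoforms, or real motif information content. Passing the
recovery suite therefore demonstrates that the statistics recover planted
parameters under the stated model — not that the thresholds are optimal for
any particular real dataset.

## Problem sizes and determinism

The test suite runs the recovery experiments at the sizes the statistics
need to be stable: 5000 peaks for co-binding and occurrence recovery
(tolerance ±0.03), 600 sequences for de novo discovery (10 restarts), 5000
genes / 1000 permutations / 200 replicate random sets for enrichment
detection and calibration. The full suite completes in about a minute on
one CPU; the acceptance script in ~10 s. All randomness flows from explicit
seeds; reports embed the configuration hash and seed, and reruns with the
same configuration are bit-identical (tested).

## Known limitations

* The hypergeometric universe defaults to the supplied annotation's genes;
  results are sensitive to that choice and the universe size is a parameter.
* Single-pass multiread allocation does not iterate to a fixed point;
  genes whose unique coverage is zero everywhere fall back to uniform
  splits.
* The ZOOPS model assumes at most one site per sequence; peaks with
  multiple true sites contribute one posterior site each.
* Whether a peak overlapping both the upstream window and the gene body
  should be recorded as one relation or two is unverifiable from printed
  descriptions of such pipelines; this package records the more specific
  relation only.
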