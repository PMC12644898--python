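# Methods

## Representation

A candidate cis-regulatory element (CRE) is represented as a bag of
motifs: an integer vector `c ∈ Z₊^M` counting retained occurrences of
each of `M` position weight matrices, with order, spacing, strand and
overlap structure discarded. The representation is deliberately
minimal; everything downstream (classification, attribution, transfer,
design) operates on counts alone.

## CRE definition

Coordinates are 0-based half-open internally (BED native; GTF/GFF3
converted on read). Peaks are centered on their summit when one is
recorded, otherwise on the interval midpoint, and trimmed/extended
symmetrically to a fixed window (default 500 bp). The distal filter
measures the distance from the nearest *window edge* to every
transcription start site and requires it to exceed 1 kb — the stricter
of the plausible readings of "more than 1 kb from a TSS". "Non-exonic"
means zero overlap with any annotated exon of any transcript. Windows
running past a chromosome end are dropped rather than shifted, so the
fixed width is unconditional. The operation is idempotent: re-filtering
its own output changes nothing.

Flanking negative sets tile fixed-width windows (default 500 bp, 50-bp
stride) through ±2 kb of each *original* CRE interval; any window
overlapping any input CRE is discarded. For one isolated CRE this
yields 31 windows per side (`(2000 − 500)/50 + 1`), 62 in total.

## Motif scanning and p-values

Scores are log2 odds with a background-proportional pseudocount
(`α = 0.1`, FIMO's convention): position `i`, base `b` contributes
`log2((p_ib + α q_b) / ((1 + α) q_b))`. Both strands are scanned; a
reverse-strand hit is reported in forward coordinates with the matched
text as read on the hit strand. Windows containing `N` are skipped
entirely (scoring them against the background would make hit sets
depend on masking conventions).

P-values are exact under the 0-order background for the *discretized*
score: per-position scores are rounded onto a shared integer grid
(1000 bins spanning the motif's achievable score range, configurable),
and the null distribution of the integer total is obtained by
convolution across positions. The scanner computes window scores on the
same integer grid, so tail lookups are exact rather than bounded — the
dynamic program reproduces exhaustive enumeration over all `4^w` words
to 1e-9 for widths ≤ 8 (tested). The float log-odds score is reported
alongside for ranking and tie-breaks.

Hits passing `p ≤ 10⁻⁴` are Benjamini–Hochberg adjusted per motif
across all sequences in the run and kept at `q ≤ 0.5`. BH is a
deliberate, documented divergence from FIMO's internal q-value
estimator (which is not plain BH and is not specified by a closed
formula); the lenient cutoff reflects the finding that degenerate,
low-affinity matches contribute predictive signal. Palindromic motifs
produce double hits (one per strand) at the same location; both are
counted by default. Optional overlap removal sorts hits per sequence by
start and repeatedly removes the lowest-scoring hit still involved in
an overlap (exact score ties broken by a seeded uniform choice) until
the retained set is pairwise disjoint; the default pipeline does *not*
remove overlaps.

## Dataset assembly

Counting conserves hits exactly; CREs with zero retained hits are kept
as all-zero rows (exclusion is configurable but not the default — an
unannotated element is still a valid, maximally uninformative
observation). Binary datasets pair a positive class (required to have
at least 100 rows) against an equal-size background stratified over the
other classes: each background class contributes
`k = ⌊n_pos / n_classes⌋` rows, the remainder filled one row each from
the largest classes so contributions never differ by more than one. If
some class has fewer than `k` rows, `k` drops to the smallest class
size and the positives are downsampled to `k · n_classes`; if the
remainder cannot be filled, positives shrink by the shortfall instead.
Splits are 60/20/20 (train/validation/test), seeded, stratified per
label by largest-remainder allocation. All sampling seeds are recorded.

A count-subsampling perturbation removes an exact fraction of
individual hit-units uniformly without replacement, for sensitivity
analyses of the motif annotation.

## Models

Gradient-boosted decision trees (XGBoost) in four modes sharing one
hyperparameter set: up to 10,000 rounds, learning rate 0.01, maximum
depth 6, 50% row and column subsampling, early stopping after 100
rounds without validation improvement. Binary models use logistic loss
(the early-stopping metric for the binary case is logistic loss on the
validation set — the multiclass metric is mlogloss and the binary one
had to be chosen; it is configurable), multiclass softmax probabilities,
multilabel one binary ensemble per class (negatives rebalanced per
label), regression squared error with RMSE. Predictions at probability
≥ 0.5 are positive. Training is single-threaded by default so fixed
seeds give bit-identical models; multithreading is opt-in. A model
scores any matrix sharing its motif vocabulary: missing motif columns
are imputed as zero counts (a motif never scanned is indistinguishable
from absent), unknown extra columns are rejected unless strict mode is
off.

## Attribution

Shapley values are computed per CRE and motif in margin (log-odds)
units, where the efficiency axiom is exact for tree ensembles. The
default background is the training-data distribution via the boosting
library's tree-path TreeSHAP. Passing an explicit reference vector
switches to exact interventional attributions computed in-package: for
each tree and leaf, the path constraints partition features into a set
that must take the instance's value and a set that must take the
reference's; the leaf's value then contributes closed-form Shapley
weights `±a!b!/((a+b)! · a or b)` of the corresponding unanimity game.
A brute-force subset-enumeration oracle (≤ 12 features, `2^n`
evaluations) verifies both routes. Global importance is the sum of
absolute Shapley values per motif (mean also reported; identical
ordering at fixed n), ties broken lexicographically; local explanations
report the top-k motifs of one CRE with signed values and raw counts.
Explanations are computed on the evaluation split by default.

## Cell assignment

Marker peaks (peak → class map) are scored by a trained model's
attributions. Per cell: peaks with accessibility > 0 count as
accessible (for binary matrices this is "exactly 1"); peaks used in
training or validation are excluded first; cells with fewer than 20
accessible marker peaks are dropped; each peak contributes only under
its own class's attribution slice (all-slice aggregation behind a
flag). The per-cell mean attribution (motif × class) is normalized by
the cell's total absolute attribution. The assignment statistic is
`r = Σ max(φ̄,0) / Σ |φ̄|` per class (0 when a class carries no mass),
z-scored *across cells within each class column* — this axis corrects
class-specific ratio baselines; the within-cell alternative is
available behind a flag — and the predicted label is the argmax of z
(falling back to raw r when a column is degenerate or only one cell is
scored). Cell types with more than 1000 annotated cells can be
downsampled to 1000. Filter accounting (input = dropped + scored) is
attached to every aggregation.

## Synthetic element design

The top-k motifs (default 5) by global ranking are implanted, two
copies each by default, into a fixed-length template (260 bp in the
examples): a seeded permutation of the instance multiset is placed at
uniform random non-overlapping positions, *replacing* template bases so
the final length never changes (a fixed final length implies
replacement, not insertion). Instances are PWM consensus strings
(argmax per column, ties A<C<G<T) by default; seeded sampling from the
PWM is optional, as the realization of instances from matrices is a
genuinely open choice. Forward-strand implantation is the default.
Every design is verified by re-scanning: each implant must be
recoverable at its recorded coordinate.

## Synthetic data

The fixture generator emulates the pipeline's inputs, not chromatin
biology. Random PWMs draw each column from a Dirichlet with the
consensus base's concentration boosted (default 50, giving ~0.94 mean
consensus probability — strong but not degenerate sites); widths
default to 8–12 so that a consensus match can clear `p ≤ 10⁻⁴` (a
perfect width-7 match sits at 6.1e-5; width 6 cannot reach the
threshold at all). CRE sequences are i.i.d. 0-order background at GC
0.41 (mouse-like); per class and motif, a Bernoulli implant places one
PWM-sampled instance at a uniform non-overlapping position, recorded in
a truth table. The flagship recovery benchmark uses two classes × 500
CREs × 500 bp, five discriminative motifs at implant rates 0.8 vs 0.05,
and twenty decoys shared at rate 0.3 — a rate chosen once as a
realistic level of shared motif occurrence.

Toy accessibility matrices are binary with block structure: a cell
accesses its own type's marker peaks with probability 1 − dropout and
other types' with the contamination probability.

What passing these tests shows: the implementation recovers planted
combinatorial signal and satisfies its contracts. What it does not
show: performance on real chromatin, where motif co-occurrence is
correlated, backgrounds are repeat-rich and non-stationary, peak
boundaries are noisy, and class labels are themselves model outputs.
The i.i.d. background in particular makes scanning specificity look
better than it is on real genomes.

## Numerical choices and limitations

- Score discretization at 1000 bins bounds p-value granularity at about
  1/1000 of the score range per motif; raise `resolution` for sharper
  tails.
- auROC uses the Mann–Whitney convention (ties half credit); auPR uses
  step-wise interpolation without linear segments. Degenerate
  denominators yield MCC = 0 / F1 = 0 with a `degenerate` flag rather
  than NaNs, and single-class inputs report missing AUCs with a
  warning.
- Determinism end-to-end requires single-thread training; the count
  matrix, splits, sampling and design stages are integer-RNG seeded and
  platform-stable.
- Problem sizes in the test-suite and acceptance runs (hundreds of CREs
  per class, tens of motifs) are chosen to exercise every code path at
  desk scale; the library itself is vectorized and handles
  database-scale motif sets (~2,000 PWMs) by streaming per motif.
- Higher-order backgrounds, motif discovery/clustering, peak calling,
  differential accessibility and alignment-based cross-species mapping
  are out of scope; labels and marker-peak maps are inputs.
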