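# Methods

This note documents the statistical and numerical choices behind the
package, in the spirit of a model-description appendix: what is computed,
under which conventions, and where the design was genuinely open.

## Scoring

**Aggregation within a slice is the mean, not the sum, of transformed
non-missing components.** The convention that missing values are simply
ignored leaves the aggregation rule open; the mean keeps slices with
different component counts on one scale and makes an entity's score
orthogonal to how much data it has — absence of evidence is carried by the
separate missingness channel (drawn as the profile's inner circle), not by
a deflated score. An entity with every component of a slice missing gets
raw value 0 and missingness 1.

**Slice rescaling divides by the column maximum** rather than min-max
normalising. All transforms map retained (nonnegative) inputs into
[0, ∞) with a meaningful anchored zero; dividing by the maximum preserves
that zero, guarantees each informative slice column attains 1, and leaves
identically-zero columns at 0. Consequently the overall score — the
weight-normalised average of slice scores — always lies in [0, 1] and is
comparable across models, and it is invariant under rescaling all weights
by a positive constant.

**Transforms.** Five parameter-free options per slice: `linear` t(x)=x,
`linear_inverted` t(x)=max−x, `log10` t(x)=log₁₀(x+1), `log10_inverted`
t(x)=log₁₀(max+1)−log₁₀(x+1), `sqrt` t(x)=√x, where `max` is the metric's
maximum over non-missing entities. The +1 offset makes zero representable
under logs; the inverted variants serve potency-type metrics where smaller
raw values mean greater concern. Transforms attach per slice (all of a
slice's metrics share one transform).

**Ranks** are descending by overall score with exact ties broken by
ascending entity id — an arbitrary but total and reproducible order.
Score arithmetic is double precision; internal equality checks use 1e-12
absolute tolerance.

## Bootstrap confidence intervals

The resampling unit is the within-slice component set of each entity: a
replicate redraws, with replacement and at the observed size, the
non-missing transformed components of every (entity, slice) cell and
recomputes the slice mean. This attaches an interval to every slice of
every individual profile — resampling entities could not do that. Each
replicate then re-runs the full pipeline (column-maximum rescaling,
weighted overall scores, ranks), so replicate quantities respect the
unit-interval invariants; rank intervals come from the replicate rank
distribution.

**Endpoints are expanded percentiles.** A slice typically holds only a
handful of components; the plain bootstrap distribution of a mean at
resample size *p* is too narrow by √((p−1)/p) and carries no t-correction,
which measurably undercovers (≈0.82–0.85 observed at p=5 against a nominal
0.95). Following Hesterberg's small-sample expansion, the per-tail
probability is widened from α/2 to Φ(−√(p/(p−1))·t_{p−1,1−α/2}),
per (entity, slice) cell; this restores near-nominal coverage
(≈0.90–0.92 measured at p=5) and converges to the plain percentile
interval as *p* grows. Overall-score and rank intervals mix cells with
different component counts, so no single degrees-of-freedom applies; they
use plain percentile endpoints. All intervals are finally expanded, if
needed, to contain the point estimate, so lo ≤ point ≤ hi holds by
construction. A single present component, or identical components, gives a
zero-width interval (resampling a singleton is the identity).

Defaults: level 0.95, 1000 replicates, and an explicit seed is required —
there is no silent clock seeding anywhere in the package. Raw-scale
(pre-rescaling) intervals are reported alongside (`raw_lo`/`raw_hi`): the
data-generating slice mean lives on the raw scale, so coverage diagnostics
use these.

## Hierarchical clustering

Entities are clustered on their slice-score vectors with Euclidean
distance. Agglomeration follows the Lance–Williams recurrence with six
linkage methods matching the classic hclust family: single, complete,
average (UPGMA), McQuitty (WPGMA), centroid, and Ward. The Ward variant is
the "D2" convention — squared Euclidean distances internally, heights
reported back on the distance scale — the variant consistent with raw
Euclidean input; centroid likewise operates on squared distances and may
produce height inversions, while the other five are monotone. When several
pairs tie at the minimum distance the pair with the lexicographically
smallest (left, right) representatives merges first, a cluster being
represented by its smallest original entity index; reference
implementations may differ at exact ties, which is why oracle comparisons
use continuous random data. Leaf order places the subtree containing the
smaller minimum original index on the left, giving a deterministic
crossing-free drawing. Clusters come from a top-down cut (smallest height
yielding k clusters, labels numbered 1..k in leaf order), from explicit
branch selection, or from k-means; dendrograms export to Newick with
branch lengths derived from merge heights.

The implementation is a direct O(n³) full-matrix agglomeration — ample for
the interactive problem sizes this package targets (≈1 s at n = 1000).

## K-means

Hartigan–Wong, the variant minimizing within-cluster sum of squares via
optimal-transfer sweeps (every point against every cluster, move if
n₂‖x−c₂‖²/(n₂+1) < n₁‖x−c₁‖²/(n₁−1)) alternating with quick-transfer
stages (each point against only its closest and second-closest clusters),
centers updated incrementally, convergence when a full optimal-transfer
pass moves nothing, capped at 100 sweeps with a warning. The classic
live-set bookkeeping of the reference Fortran is an efficiency device, not
a semantic one, and is omitted. Initial centers are n_clusters distinct
random entities; each of n_start restarts draws from one seeded generator
stream (NumPy PCG64 with the user's seed), a start whose initial
assignment empties a cluster is redrawn, and the restart with the smallest
total within-SS wins. Reported centers are exact member means; totss =
tot_withinss + betweenss holds to numerical precision.

PCA display coordinates use the sample covariance (divisor n−1) without
column standardization — slice scores already share the unit interval.
Component signs are fixed by making each component's largest-magnitude
loading positive; the user-facing flips then negate axes explicitly.
Rank-deficient input yields a zero second component.

## Rendering

Figures are flat lists of geometric primitives in pixel coordinates. The
SVG writer serialises them with fixed 6-decimal formatting and no
generated ids or timestamps, so SVG bytes are a pure function of the
inputs (golden-file testable); PNG paints the same primitives through
matplotlib Agg at a configurable DPI (default 300), so bit-exactness is
promised only for SVG. Profile slices start at 12 o'clock and proceed
clockwise in model order — the original tool's convention is not stated
anywhere, so this one is fixed and documented. Arcs longer than a quarter
turn are emitted as chained ≤90° segments for numerical robustness.
Confidence bands blend the slice color 55% toward white; the missingness
inner circle (18% of the profile radius) uses grayscale luminance linear
in (1 − missingness), darker = more missing. Circular dendrograms with
`distribute` space leaves uniformly at 2π/n; profile leaves auto-downgrade
to text labels above 500 leaves.

## File formats

Four CSV dialects (UTF-8, RFC 4180 quoting): a bare matrix with row and
column names; a row-annotated matrix with an entity `class` column; a
column-annotated matrix whose leading rows tag per-metric annotations
(`slice`, `weight`, `color`, `transform`); and the round-trippable
*complete* file this package writes — `#`-prefixed slice metadata lines
(`# slice: <name>, weight=<w>, color=<#RRGGBB>, scale=<transform>`,
`# metrics: m1|m2|...`) above an `id,class,<metrics...>` matrix. Dialect
auto-detection keys on those reserved markers. Only the complete dialect
reconstructs a model; column annotations are validated and surfaced in the
import report. Floats are serialised as shortest round-tripping decimals,
so weights and values survive write→read bit-for-bit. The only missing
token is the case-sensitive `NA`; any other non-numeric cell is a hard
error naming its row and column. Zero is retained — only strictly negative
values are converted to missing. When merging multiple files, entities
union, metrics intersect, a present value fills a missing one, and two
conflicting present values are a hard error. No byte-compatibility with
the legacy GUI's format is claimed.

## Synthetic data

The generator emulates assay-style inputs: positive right-skewed values
(log-normal, σ=1), seeded NA and negative cells at configurable fractions
(defaults 5% / 2%), and three-class entity annotations. The `uvcb_model`
fixture reproduces the *structure* of a published petroleum-substance
model — 25 entities, four equally-weighted slices of 8/3/5/2 metrics
colored yellow/blue/dark-gray/red — as a synthetic stand-in; it carries
none of the original measurements. `blobs` produces well-separated
Gaussian clusters (σ=0.01, unit center separation) for exact-recovery
tests. What passing tests show is therefore internal consistency and
oracle agreement on data with the right shape; real assay data differ in
correlation structure between metrics, systematic (non-random)
missingness, and heavier measurement-error tails, none of which the
generator models.

## Problem sizes and budgets

Test and acceptance runs use the sizes the analyses were designed around:
random property sweeps at n ≤ 10 entities × ≤ 8 metrics (1,000 instances),
linkage oracles at n = 12 (100 instances × 6 methods), coverage at 10
entities × 5 components × 2,000 replicates × 200 repeats, and one
full-pipeline run at 1,000 entities × 18 metrics with B = 1,000 — the
scale at which the original interactive tool reports only a momentary
pause, and which completes here in well under a minute.

## Known limitations

- No per-metric weights within a slice, no z-score standardization, and no
  per-metric directionality beyond the inverted transforms.
- Bootstrap intervals quantify within-slice component variability only;
  they do not propagate assay measurement error supplied externally.
- The six linkage methods are the fixed set above; alternative distances
  are out of scope (Euclidean is the method's definition here).
- k-means model selection (silhouette, gap statistic) is deliberately
  absent; the user supplies the cluster count.
- PDF figure output is not provided; SVG is the vector format of record.
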