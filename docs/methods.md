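# Methods

`pigback` re-creates, as a tested library, a contact-free pipeline for
estimating the body weight of large sows from overhead depth recordings:
denoise the raw 3D point cloud, isolate the animal's back, measure six
body-size parameters from it, and regress weight with a small convolutional
network. This note documents the models and procedures, their assumptions,
the synthetic data that stands in for farm recordings, and the numerical
choices made where the design was open.

## Scene model and coordinate conventions

All clouds are unordered `(x, y, z)` triples in metres with `z` the height
above the floor plane. A depth camera is assumed to hang ~2.5 m straight
above a weighing passage ~1.7 m wide; converting sensor depth to height is
out of scope — the pipeline only ever sees heights. Point order never
carries meaning; every stage is order-invariant up to documented tie rules.

## Denoising

Raw overhead clouds carry two noise populations: sparse *large-scale*
outliers hovering off the body (reflections, dust, partial returns) and
dense *small-scale* clumps offset from it. Two complementary filters remove
them.

**Statistical k-NN filter** (large-scale). For each point, the mean
Euclidean distance d̄ᵢ to its k nearest other points is computed with a k-d
tree; a point is deleted iff d̄ᵢ strictly exceeds

    L = mean(d̄) + σ · std(d̄),

with the sample standard deviation (n−1). Defaults `k=30, σ=2`, the values
selected in the field study this pipeline follows. Equality at L retains the
point (the least destructive reading of the rule); neighborhoods never
include the query point, which would bias d̄ᵢ toward zero.

**DBSCAN** (small-scale). Classical density clustering with the
ε-neighborhood counted *including* the point itself against `MinPts`.
Defaults `eps=0.02 m` (the field-selected value) and `min_pts=10`; `min_pts`
is not reported in the source study — 10 is a density-robust choice for the
~7 mm ground-sampling pitch these scenes have, and it is exposed as config.
Clusters are numbered 1, 2, … in seed-discovery order (noise is 0); a point
first marked noise becomes a border point when a later expansion reaches it,
and a border point reachable from several clusters belongs to the earliest
created — the only order dependence the algorithm has. The implementation is
vectorized (core graph + connected components) but reproduces the literal
seeded expansion exactly; the test suite enforces bit-equality against a
brute-force expansion and cross-checks core/noise sets against
scikit-learn.

**Pig-cluster selection.** The source study does not state how the pig
cluster is picked from the DBSCAN output. Chosen rule: among clusters of at
least `min_size` points (default 200) whose mean height exceeds the floor
level by `floor_margin` (default 0.1 m), take the one of greatest mean
height. Elevation, not size, is the criterion because the floor is normally
the largest cluster in an overhead scene. The floor level is the modal
height (1 cm bins) of the largest cluster when that cluster is flat
(z-spread < `floor_margin`), else the 1st percentile of all heights.

## Back isolation

The pig cloud is projected to the plane and rotated about z so its
minimum-area enclosing rectangle (rotating calipers over convex-hull edge
directions) is axis-parallel, long side along x. The rotation is rigid and
its angle is reported in degrees in (−90°, 90°].

The planar outline is an **alpha-shape boundary**: Delaunay triangles with
circumradius ≤ α are kept and the outer boundary loop of their union is the
outline polygon (CCW). The source study never states its outline
construction; the alpha shape was chosen because it is parameter-light and
degrades to the convex hull on convex shapes. Default α = 3× the median
nearest-neighbor spacing. An α too small to connect the shape raises an
error suggesting a larger value.

**Sag profile and head/tail split.** For each outline vertex, the *sag* is
its perpendicular distance to the convex-hull edge spanning it in traversal
order (hull vertices have sag 0). Deep sags mark the neck and tail-root
notches. Candidate split points are the cyclic local maxima of the sag
profile (plateau runs merged, one candidate per notch) of depth ≥ `sag_min`
(default 0.03 m). With the head direction known and fixed (a flag; the
simulator guarantees +x), the dividing axis is the vertical line through the
projection centroid: the head cut is the candidate *closest* to the axis on
the head side — the neck notch sits closer to the body centre than the snout
— and the tail cut the candidate *furthest* from it on the tail side. Points
strictly between the two cuts survive. A side with no qualifying candidate
is left uncut, with a warning recorded in the result; this happens on a few
percent of synthetic scenes whose tail notch is shallow, and the downstream
features degrade gracefully (the tail is small).

## Voxel downsampling

Cubes of side `r` (default 0.005 m) anchored at the coordinate minima, with
`ceil((max−min)/r)` cubes per axis; each occupied cube is replaced by the
centroid of its points, labels by majority vote (ties → `unknown`). The flat
index is `h = hx + hy·Dx + hz·Dx·Dy` with half-open cubes and upper-boundary
clamping; output is ordered by ascending `h`, and centroids are summed in a
canonical order so the result is bitwise invariant to input permutation.
Downsampling runs after the head/tail trim, so only the back of interest is
reduced. The achieved rate is data-dependent and logged, never asserted.

## Back features

Six parameters per back cloud:

* **envelope volume / envelope area** — volume and facet area of the 3D
  convex hull (qhull);
* **projection area** — shoelace area of the *concave* outline (not the
  hull), so the trim is reflected;
* **shoulder / belly / hip width** — the body x-range is split into three
  equal thirds; in each third the outline vertex of maximal y is paired with
  the vertex of minimal y, and the widths are the pair separations, ordered
  anterior → posterior. The source study names six key points but never
  defines them constructively; the thirds rule is this package's declared,
  config-free interpretation. Ties in extremal y (exactly collinear edges)
  resolve to the vertex nearest the third's centre.

All six are translation-invariant and scale as s, s², s³ under uniform
scaling (tested to 1e−6). Pearson correlations between features across a
herd are available as a 6×6 table.

## Weight models

**Input encoding.** Each back cloud becomes (a) a 64×64 *height raster* —
mean height above the cloud's lowest point per cell of the x-y bounding
rectangle, empty cells 0 — and (b) the six-feature vector. Both views feed
the CNN: the raster through the conv stack, the features concatenated at the
first fully connected layer. A features-only mode drops the conv stack for
ablation.

**CNN.** conv(8 filters, 3×3) → pool → conv(16, 3×3) → pool → flatten ⊕ 6
features → FC(64) → FC(1), ReLU throughout, implemented directly in numpy.
Pooling is a 2×2 *mean*-pool with a learnable per-channel scale β and bias B
applied to the pooled map (β·down(χ)+B), then the activation — the
down-sampling layer is weighted and biased, not a plain max-pool. Training
is plain full-batch gradient descent on MSE with rasters (global z-score),
features (per-column z-score) and target (z-score) standardized and restored
at prediction. Defaults: learning rate 0.01, 250 epochs, He initialization
from a seeded generator; training is bit-reproducible per seed. Larger rates
(0.03+) can diverge on ~140-sample fits — the loss turns non-finite and a
`DivergenceError` names the rate. The loss history is recorded; plain GD
does not guarantee monotone decrease, only final < initial is asserted on
fixtures.

**RBF baseline.** A Gaussian radial-basis network on the six features:
centers are a seeded random sample of training vectors (default 40), the
shared width is the median pairwise center distance, and output weights are
solved by linear least squares (min-norm for underdetermined systems; ridge
fallback with a warning only if the solve fails). It is the features-only
comparison model, deliberately simple.

**Metrics.** MAE (kg), MAPE (%) and RMSE (kg) between estimated and actual
weights, with MAPE undefined (error) at zero actuals. RMSE ≥ MAE always
(power-mean inequality; property-tested).

## Synthetic scenes

Real recordings of the 198-sow herd are not available, so a generator
produces labeled stand-ins with known weight:

* **floor**: a jittered grid at z ≈ 0 over 2.5 × 1.7 m;
* **torso**: the upper half of a superellipsoid (exponent 2.5 — flatter,
  more pig-like than an ellipsoid), apex at `body_height`, sampled on an
  (x, y) grid at `pitch` (default 0.007 m ≈ a 640×480 depth sensor at
  2.5 m). Two visibility rules emulate the overhead camera: the surface is
  clipped below a ground `clearance` (default 0.30 m — the flanks below
  belly height are occluded; the animal stands on legs the features never
  use), and points whose local slope exceeds 3.5 (incidence beyond ~74°) are
  dropped, as grazing returns are on real sensors. Without these rules, grid
  sampling would place steep-flank points at artificially sparse 3D density
  that no physical scan has, poisoning the density-based stages;
* **head and tail**: narrower, lower superellipsoid lobes overlapping the
  torso ends (+x head, −x tail), so the union is density-connected and the
  outline carries genuine neck/tail notches;
* **large-scale outliers**: 300 uniform points in the body's 0.3 m-dilated
  bounding box, rejection-sampled to keep ≥ 5× pitch from every surface
  point (an unambiguous target for the statistical filter);
* **small-scale noise**: 5 Gaussian blobs (40 points, std 0.01 m) with
  centers ≥ 0.1 m from the body — far beyond Eps, so DBSCAN always separates
  them;
* **weight**: body dimensions are drawn uniformly from L ∈ [1.5, 1.9],
  W ∈ [0.45, 0.60], H ∈ [0.50, 0.65] m, and the true weight is affine in the
  dimension product, w = a + b·(L·W·H), with (a, b) solved so the extreme
  configurations land exactly on 190 and 300 kg — the herd range being
  emulated. A purely multiplicative rule cannot map these dimension ranges
  onto that weight range (the two intervals are not proportional), hence the
  affine calibration. Multiplicative Gaussian noise with CV 3% (default)
  models everything dimensions do not explain.

Scenes are bit-reproducible per seed; herds draw per-pig dimensions from
child seeds spawned deterministically from one herd seed.

What the generator does **not** model: sensor-specific noise textures,
posture variation (standing square is assumed), occlusion by pen fixtures,
multiple animals. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the stated noise taxonomy — not
performance on farm data, where posture and occlusion dominate the error
budget.

## Evaluation protocol and problem sizes

The herd experiment mirrors the source protocol at simulation scale: 198
pigs, one cloud each, 140 train / 58 test (seeded shuffle), CNN trained on
rasters + features, RBF on features, both scored on the held-out pigs. At
the default pitch a scene has ~105 k points and the full pipeline runs in a
few seconds per scene on one core; the whole protocol, training included,
completes in roughly ten minutes. `scripts/acceptance.py` runs exactly this
protocol and writes the held-out CNN MAPE.

## Known limitations

* The six key points and the pig-cluster selection rule are interpretations
  of underspecified steps; both are documented above and config-exposed
  where reasonable.
* The outline tracer assumes the alpha-shape boundary of a dense, simply
  connected shape; sparse or fragmented clouds fail loudly rather than
  producing a bad polygon.
* Plain full-batch gradient descent is faithful to the described training
  but is the least forgiving optimizer; the default learning rate is chosen
  for stability, and divergence raises rather than silently degrading.
* MAPE on synthetic herds reflects the 3% weight noise floor plus feature
  extraction error; it is not comparable to farm-data error figures.
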