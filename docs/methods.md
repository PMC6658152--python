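# Methods

This note documents the models, numerical choices and known limitations of
`fundusgraph`. It complements the README, which shows what the package
computes; here we explain how and why.

## Vessel graph model

The retinal vasculature in a fundus photograph is modelled as an undirected
weighted graph. Nodes are bifurcation points (skeleton pixels with ≥ 3
neighbours, 8-connectivity) and vessel endpoints (1 neighbour); links are
the vessel segments between them. Because the photograph is a 2-D
projection of a 3-D vessel bed, artery/vein crossovers appear as genuine
graph nodes and can close cycles; these are retained deliberately — the
same projection artifacts occur in every image of a cohort, so pairwise
comparisons remain fair. Crossover disambiguation and pruning of 4-link
nodes are explicitly out of scope.

Per link: `L` is the number of skeleton pixels spanned (diagonal steps are
not √2-weighted — a deliberate convention that keeps lengths integral and
reproducible), `N` is the number of raw-mask pixels assigned to the link by
nearest-labelled-skeleton-pixel (Euclidean distance transform), and
`W = N / L ≥ 1`. The link weight is `w = L**l * W**a`. The exponent pairs
computed by default, each with a physical reading:

| method | (l, a) | weight meaning |
|---|---|---|
| C-NDD | (1, −2) | flow resistance (Poiseuille ∝ L/W²·…) |
| C-NDD | (1, 2)  | vessel volume (∝ L·W²) |
| CMWD  | (1, −2) | flow resistance |
| WDD   | (0, 1)  | vessel width |

The *central node* is the graph node nearest the optic disc (all
transported blood enters and leaves there); assignment fails if the nearest
node is farther than 3 disc radii. C-NDD is the distribution over nodes of
the weighted shortest-path distance to the central node; CMWD divides each
distance by its hop count; WDD is the distribution of node strengths.
The central node is excluded from C-NDD/CMWD (its distance is the
degenerate 0 and its hop-mean is 0/0); nodes in components disconnected
from the central one are excluded from the path-based samples but retained
in WDD, which is purely local. Scaling all weights by c > 0 scales every
C-NDD/CMWD sample by exactly c.

### Skeletonization and junction handling

Thinning uses a topology-preserving skeletonization, so the skeleton has
the same number of connected components as the mask. Two cleanup rules,
both configurable, precede node detection:

* **Spur pruning** (default 3 px): tip branches shorter than 3 pixels
  attached to a junction are thinning artifacts and would otherwise
  dominate the endpoint count.
* **Junction clustering**: thinning produces 2×2 blobs of ≥3-neighbour
  pixels at bifurcations; touching junction pixels are merged into a single
  node at their centroid. On small hand-constructed skeletons the extracted
  graph is isomorphic to the pixel-adjacency graph with junction clusters
  merged and all degree-2 chains contracted (verified by a brute-force
  oracle in the tests).

## Segmentation

The automated segmenter is a two-stage design: enhancement then graph-based
region merging. Enhancement takes the green channel (highest
vessel/background contrast in fundus photography), estimates the background
with a large-kernel median filter evaluated at 1/4 resolution (a full-
resolution median at this kernel size is prohibitively slow and the
background is smooth by construction), subtracts, and applies
contrast-limited adaptive histogram equalization; the output is normalized
to [0, 1] with vessels bright. Felzenszwalb–Huttenlocher region merging
then partitions the enhanced image, regions brighter than an Otsu threshold
are classified as vessel, and the largest 8-connected component is kept.
Segmentation fails (and the image is recorded and skipped) when that
component covers < 1% of the image. The result is invariant to adding a
constant to the enhanced image. On synthetic cohorts the Dice overlap with
the generator's ground-truth mask is ≈ 0.88.

The optic-disc detector scores each pixel by (local brightness excess,
a difference of Gaussians that cancels the smooth illumination gradient)
× (smoothed vessel density); the confidence is the ratio of the best peak
to the best peak elsewhere, with detection declared failed below 1.2.
User-supplied disc coordinates bypass detection; expert masks bypass
segmentation.

## Fractal analysis

Box counting covers the mask with a grid of boxes of size ε anchored at
pixel (0, 0) — no grid-offset averaging, so counts are exact and testable —
with dyadic ε from 2 up to min(rows, cols)/4 by default. The dimension is
the least-squares slope of log N(ε) against log(1/ε); the largest scale is
excluded when its residual exceeds 3× the median residual (saturation
guard), and a constant table yields D = 0 with a warning. Both the raw mask
and its skeleton are fitted with identical scales, giving one point
(D_skeleton, D_raw) per image in the fractal plane.

**Finite-size behaviour.** For analytic phantoms the estimator is accurate
to the stated tolerances (filled square 2.00, line 1.00, depth-6 Sierpinski
carpet 1.893). For diffusion-limited aggregation clusters, however, the
plain slope over dyadic boxes 2…256 on a 20,000-particle aggregate gives
1.53 ± 0.04, below the literature dimension ≈ 1.71 of DLA. This is not an
implementation artifact: the mass–radius dimension of the same aggregates
is 1.66–1.73, and an independently written reference DLA gives identical
box-count values at equal size. The gap is the well-known discretization
bias of box counting on structures with one-pixel-wide arms — the local
log–log slope rises from ≈ 1.3 at ε = 2 to ≈ 1.65 at ε = 32–64 before
saturating — and shrinks only slowly with particle count. The package
reports the plain-fit value rather than a window-picked one; comparisons
between cohort groups are unaffected because the same bias applies to every
image.

## Cohort comparison

Per method, per-image sample sets are histogrammed on 64 uniform bins
spanning the pooled 0.5th–99.5th percentile of the whole cohort (a common
support is required for divergence computation). Pairs of histograms are
compared with the Jensen–Shannon divergence in natural-log units
(0 … ln 2 ≈ 0.693); the divergence itself, not its square root, fills the
N×N matrix. IsoMap embeds that matrix into two coordinates: a k-nearest-
neighbour graph (default k = 10, incremented automatically until connected,
with a warning), geodesic distances by Dijkstra, classical MDS with a
deterministic sign convention. Zero-divergence pairs are kept as explicit
zero-weight edges so duplicate images embed at the same point.

Group differences on scalar features (counts, single fractal dimensions)
use the pooled-variance two-sample t-test. For 2-D features the points are
projected onto the Fisher discriminant direction and the projections are
t-tested. Because the Fisher direction maximizes the projected t², that
statistic equals Hotelling's T², and treating it as an ordinary t is
anti-conservative (under the null with 8 + 8 points its median "p" is
≈ 0.24, not 0.5). The default p-value therefore refers T² to its exact
F(2, n₁+n₂−3) null distribution, which makes the null p-values uniform —
verified by a 200-replicate calibration test. The naive projected-t
p-value is also exposed (`p_projected`) for comparison with analyses that
use the biased convention, and testing only the first embedding coordinate
is available via configuration.

Cohorts of mixed pixel resolution are rejected unless explicitly allowed:
lengths and widths are in pixel units and are not rescaled across
resolutions, so a cohort must be analyzed at a single resolution.

## Synthetic data

The generator emulates the gross structure of a fundus photograph: a warm,
vignetted background with mild sensor noise, a bright optic disc, and dark
vessels radiating from it as a dichotomous tree with per-generation length
decay, Murray-like width tapering (child width = parent × 0.8, floored at
1 px) and jittered branch angles. Vessels are rendered as anti-aliased
capsule strokes thresholded at 0.5 intensity, producing realistic staircase
boundaries that exercise skeletonization. The ground truth — node
positions, segment lengths, widths — is kept exactly, and the mask is
exactly the rasterized segments. Segments that would leave the frame are
clipped at the border and flagged.

Disease surrogates, chosen to mirror the qualitative clinical mechanisms:
extra short thin side branches (Poisson rate per segment) emulate
neovascularization; a global width factor emulates vessel swelling under
raised intraocular pressure. Their effect sizes are free parameters; the
shipped contrast (width × 1.3) is deliberately strong so that a 15 + 15
cohort detects it with power ≈ 1, and the null (identical specs) is used
for type-I calibration. The defaults use 512² images for contrast studies
and 384² for replicated calibration (with ground-truth masks and disc
positions, since segmentation adds no group contrast), with 8 + 8 images ×
200 replicates.

What the synthetic data does **not** emulate: lesions, exudates, texture,
field-of-view borders, artery/vein intensity differences, or genuinely 3-D
crossovers (tree branches can still overlap geometrically at wide fan
angles, which is how the test fixtures with guaranteed-clean geometry are
defined). Passing tests on synthetic cohorts therefore demonstrate the
pipeline's correctness and statistical calibration, not clinical
performance on real photographs.

The DLA generator grows on-lattice aggregates: walkers born on a circle
just outside the cluster take 4-neighbour steps, stick on 4-neighbour
contact, and are respawned past a kill radius of 3× the cluster radius
(floored at 20 px). All generators are pure functions of their spec,
including the seed.

## Numerical conventions

* Pixel coordinates are 0-based (row, col); masks are single-channel.
* 8-connectivity throughout skeleton analysis; 4-connectivity in DLA.
* Histograms sum to 1 within 1e−9; out-of-range samples are clipped into
  the end bins.
* Distance ties in central-node assignment break toward the lowest node id.
* Self-loops and parallel links are retained; a skeleton consisting only of
  closed loops (no endpoint, no junction) is an error.
* All pipeline stages are deterministic; a cohort run is a pure function of
  (manifest, config), and re-running writes byte-identical tables.
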