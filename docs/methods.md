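# Methods

This note records the models, numerical choices and limitations behind
fluocell, in the order of the pipeline.

## Statistical shape model

Contours are sampled from binary masks at the 0.5 iso-level (sub-pixel,
`skimage.measure.find_contours`) and resampled to `N` arc-length-equidistant
points, oriented counter-clockwise, starting at the boundary point with the
largest x (ties: largest y). Coordinates are continuous (x, y), pixel centers
at integers, origin top-left, y down. `N` defaults to 100 for model training
(64 in the scene pipeline, where cells are small and speed matters); both are
configuration parameters, and all contours in one model must share `N`.

Alignment removes translation (centroid) and rotation (principal axes of the
point cloud). Correspondence is an exhaustive search over all cyclic shifts,
both traversal directions and the 180° principal-axis ambiguity, minimizing
the summed squared point distance to a running reference (first contour on
pass one, then the mean with a closed-form Kabsch rotation on pass two).
Scale is deliberately preserved: absolute cell size matters downstream for
placement and overlap. Exhaustive search is O(N²) per contour and exact;
collinear (degenerate) contours are rejected.

PCA uses the SVD of the centered data matrix; eigenvalues are the sample
covariance spectrum. Generation draws mode coefficients independently from
N(0, λᵢ) truncated at ±3σ — the standard active-shape-model convention, which
keeps shapes plausible at the cost of shrinking the realized per-mode
variance to (1 − 6φ(3)/(2Φ(3)−1))·λ ≈ 0.9733·λ; statistical tests compare
against the truncated value. A candidate is rejected when its mean contour
radius (mean distance of contour points from their centroid) is below
`r_min`, or when its polygon self-intersects; the minimum-size rule as a
coefficient-space test ‖b − pinv(P)·x_m‖ > r_min is available behind
`constraint="coefficient"` for fidelity, but the mean-radius form is the
default because it tests the realized shape property the constraint exists
for. A sensible `r_min` for a trained model is the training mean radius minus
about four standard deviations — low enough that rejections stay rare and do
not bias the mode statistics, high enough to exclude degenerate slivers.
More than 1000 consecutive rejections raise an error (model and `r_min`
incompatible).

## Elastic texture warp

Every mask pixel becomes a movable point. Boundary pixels (those with a
background 8-neighbour) are border points; interior pixels are bulk points;
every `fixation_stride`-th contour point (default every 4th) is a fixation
point — a sub-pixel point pinned by a spring to the corresponding target
contour point and linked by border springs to its two nearest boundary
pixels. The bulk graph links 8-adjacent mask pixels with per-edge stiffness
log(1+I(p))·log(1+I(n)) (natural log; the base only rescales `w_bulk`).

`bulk_force` returns the *gradient* of the bulk energy,
Σ k·(p−n); the relaxation steps along the negative gradient, i.e. toward the
neighbours — the direction that makes the energy a descent quantity and, in
the uniform-intensity limit, drives the interior to the graph-harmonic
extension of the border. For a disk mapped to a scaled disk the harmonic map
is the exact similarity transform, which is the oracle the tests use
(observed mean deviation ≈ 3 % of the target radius; the residual is chord
sag between fixation anchors).

Force split: border points feel fix + border springs only; bulk points feel
bulk springs only. Two consequences are worth knowing. First, the total
energy legitimately *rises* while an expanding target stretches the
zero-rest-length bulk springs; the true Lyapunov function of the sweep is the
fix+border energy, which is what the divergence detector watches (10
consecutive rises, or growth past 2× its starting value, aborts with "step
too large"). Second, the interior equilibrium is invariant to the overall
`w_bulk` scale — only the intensity *ratios* matter, which is what protects
bright regions from distortion. The optional `bulk_on_border=True` mode makes
the sweep full gradient descent on the total energy; there `w_bulk` trades
off against the fixation springs, and raising it contracts the texture and
shrinks bright areas monotonically (the weight-ablation behaviour).

Defaults: w_fix = 10, w_border = 1, w_bulk = 0.08, η = 0.05, step cap 0.5 px,
tolerance 1e-3 px, at most 5000 sweeps. The learning rate is chosen so that
the per-sweep relaxation factor η·w·Σk stays below 1 for 8-bit intensities
(stability) while the interior diffuses to equilibrium within a few hundred
sweeps; weights "have to be adapted per cell and texture type" and are
exposed in the scene configuration. Point updates are sequential in a seeded
random order (Gauss–Seidel-like, compiled with numba); runs are bit-exact
reproducible for a fixed seed. After convergence, fixation points within a
snap distance (3 px) are snapped exactly onto their targets; a warning names
any that are not.

Rasterization splats each point's source intensity at its rounded final
position (coincident deposits averaged), fills empty in-mask pixels by
inverse-distance weighting of the 8 nearest deposits, and zeroes everything
outside the target polygon. Both splat-averaging and IDW are convex, so
output intensities never leave the source range. An identity warp of a
pixelated patch is *not* exactly at spring equilibrium (staircase corners
feel net border forces), so the ring redistributes tangentially by up to a
pixel; the rasterized output is still exact for uniform textures and within
one gray level for the identity splat. A warp whose deposits cover less than
half of the achievable in-mask coverage (min(1, points/mask pixels) — an
expanding warp cannot fill more pixels than it has points) aborts as
collapsed.

Per simulated cell, the texture patch is drawn uniformly from the pool
filtered to areas within ±50 % of the target shape's area, falling back to
the closest-area patch; this limits the strong-stretch regime where small
patches map onto large shapes.

## Placement

Cluster centers are uniform within the image with a margin of the largest
cell radius. Cluster assignment is balanced-random: cluster sizes differ by
at most one and the order is shuffled, so with as many clusters as cells
every cell is alone at its own center. The first cell of a cluster sits at
the center; each later cell starts there and moves outward in `step`-px
(default 1) increments along a random direction until its maximum Jaccard
against *all* already-placed cells is ≤ J_max ("adjacent cells" is read
scene-wide — the safe superset that makes the global bound exact), retrying
up to 32 directions before declaring the layout infeasible. Cells always end
fully inside the image, which keeps the ground truth complete. The bound is
inclusive (≤ J_max, so J_max = 0 means pixel-disjoint); a strict mode
implements the "drops below" reading for J_max > 0. The isolated preset adds
a 2-px minimum background gap via dilation.

## Scene composition

Pipeline order: Perlin background → cells → Gaussian noise → clip to the bit
depth (default 8; tables are on the 0–255 scale). The background is classic
lattice-gradient noise with smoothstep interpolation, octave-summed with
amplitude halving and frequency doubling, then min-max scaled to
[offset, offset+amplitude] — written in-package because no installed library
provides 2-D gradient noise. Overlaps are additive by default (fluorescent
intensities of stacked cells add); a maximum mode exists for comparison, and
background cells are not blurred in overlaps. The label map stores the
topmost cell per pixel; the full per-cell masks ride along in the ground
truth so overlaps are recoverable. The clipped-pixel fraction is recorded and
warns above 1 %.

Per-image sub-seeds derive from the master seed (all below 2³¹) and are
recorded in the manifest. The overlap series reuses the *same* sub-seeds per
degree, so each degree draws identical cells, textures and background and
differs only in placement — isolated and touching datasets are then
pixel-identical up to cell position, which is what makes the intensity-trend
property exact rather than statistical.

## Measurements

Mean cell intensity averages each cell's interior mean, cells weighted
equally regardless of size; SMD is the per-cell mean absolute deviation from
the cell's own mean, averaged over cells. A pixel inside two overlapping
cells contributes to both cells' sums (the formula indexes pixels per cell).
Dataset summaries average per image first, then across images. SMD is
invariant to adding a constant to the image and scales linearly with
intensity rescaling; both laws are property-tested, and a brute-force
pixel-loop oracle checks the implementation on small fixtures.

## Segmentation harness

DoG band-pass (σ_low, σ_high) → k-means (k clusters, fixed seed, fit on at
most 20 000 sampled pixels, predicted everywhere) → brightest cluster(s) as
foreground → marker-based watershed on w·edge + (1−w)·(1−normalized distance
transform), markers from distance-transform maxima (hybrid) or supplied seed
points (seeded) → components under a_min removed. Because k-means partitions
even a featureless image, a guard rejects all foreground when the band-passed
image is not right-skewed (skewness < 0.3): fluorescent cells are
bright-on-dark and push the DoG skewness far above 1, while blank noise and
smooth background stay near 0.

The combined Jaccard matches predicted to ground-truth cells one-to-one,
greedily by descending pairwise Jaccard, and divides the summed matched
scores by max(n_pred, n_gt), penalizing both false splits and false merges;
it equals 1 iff the labelings are pixel-identical up to relabeling. The
definition is isolated in one function so an alternative matching (e.g.
Hungarian) is a local swap.

Parameters are tuned by cyclic coordinate descent over configurable grids
(σ in half-pixel steps, k ∈ {2,3,4}, w in 0.1 steps, a_min log-spaced by
default), with memoized scoring and a 1e-4 per-cycle improvement threshold;
invalid combinations (σ_high ≤ σ_low) are skipped. Cross-validation shuffles
images with a seed into near-equal folds, optimizes on the training split and
scores the held-out split.

One caution from the benchmark experiments: "isolated" and "touching" both
have zero realized overlap, so their population scores are statistically
indistinguishable (~0.005 apart under ~±0.03 small-fold CV noise); the
overlap-trend claims that are actually forced by the mechanism are the
orderings across distinct overlap levels, and that is what the tests assert.

## Synthetic data

The procedural patch generator emulates the input the simulator expects from
annotation: single-component masks with simple boundary polygons and three
texture families — uniform (protoplast-like), radial-gradient (membrane
stains fading toward the rim) and speckle (bright granules on dim plasma).
Blob outlines are band-limited radial perturbations of a circle (harmonics
2–6, bounded amplitude), which guarantees star-shaped hence simple polygons.
Default radii 10–16 px and peak intensities 80–180 give realistically sized,
clearly resolvable cells at the 96–128 px image sizes used throughout the
tests; those sizes keep the full suite and the acceptance script fast while
exercising every code path at realistic cell-to-image ratios.

What the fixtures do *not* emulate: optical point-spread blur, shading and
illumination artifacts, dye debris, multi-channel coupling (e.g. a DAPI
channel co-registered with cytoskeleton), or the shape complexity of real
macrophages. Passing tests therefore demonstrate the correctness and the
internal trends of the simulator and harness, not segmentation performance
on real micrographs.

## Known limitations

- Heavily concave target shapes can leave the star-shaped assumption of the
  fixture generator; the warp itself handles them, but fixation-point
  spacing (stride 4) may under-constrain deep lobes.
- The warp maps one source patch per cell; it cannot synthesize texture
  detail beyond what the patch contains, and strong expansions dilute
  granule density.
- Placement treats cells as rigid stamps; there is no adhesion or packing
  model, and very high J_max with many cells can exhaust the direction
  retries.
- The skewness guard assumes bright-on-dark fluorescence; inverted-contrast
  imaging would need the sign flipped.
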