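# fluocell

Simulation of photo-realistic fluorescence cell micrographs with pixel-exact
ground truth, plus the objective measurements and segmentation harness needed
to benchmark cell-segmentation pipelines against that truth.

Hand annotation of fluorescence micrographs is slow, subjective and nearly
impossible where cells overlap — yet overlapping cells are exactly where
segmentation algorithms disagree most. A simulator that learns cell shape and
texture from a small set of annotated cells and then composes arbitrarily
many images *with known per-pixel truth* turns segmentation evaluation into a
controlled experiment: the degree of cell overlap becomes an experimental
variable instead of an annotation artifact.

## The model

**Shape.** Annotated cell outlines are sampled with *N* arc-length-equidistant
points, centered, rotated onto their principal axes and brought into
point-to-point correspondence. PCA of the aligned coordinate vectors gives a
mean shape **x**ₘ and orthonormal modes **P** with eigenvalues λᵢ; new outlines
are drawn as

&nbsp;&nbsp;&nbsp;&nbsp;**x** = **x**ₘ + **P b**,&nbsp;&nbsp; bᵢ ~ N(0, λᵢ) truncated at ±3σ,

rejecting candidates whose mean contour radius falls below a minimum size
r_min (an active-shape-model with a size guard).

**Texture.** The texture of an annotated cell is treated as an elastic tissue
spanned between fixation points and relaxed onto the generated outline by
minimizing

&nbsp;&nbsp;&nbsp;&nbsp;E = w_fix·E_fix + w_border·E_border + w_bulk·E_bulk,

where E_fix pins every *k*-th contour point to its target, E_border is a
spring chain along the boundary, and E_bulk couples 8-connected interior
points with intensity-dependent stiffness — the gradient of E_bulk at a point
**p** is Σₙ log(1+I(**p**))·log(1+I(**n**))·(**p**−**n**), so bright regions
are stiff and resist distortion. Relaxation is seeded-random-order gradient
descent with a per-step displacement cap; the relaxed points are splatted back
to the pixel grid and holes are filled by inverse-distance interpolation.

**Placement.** Cells are assigned to clusters; each cell starts at its
cluster center and moves outward along a random direction in 1-px steps until
its Jaccard overlap with every already-placed cell drops to the bound J_max.
Presets cover the overlap series *isolated → touching → overlapping →
overlaying* (J_max 0 / 0 / 0.15 / 0.40).

**Scene.** image = clip(Perlin background + Σ cells (additive in overlaps) +
Gaussian noise). Every scene carries an instance label map plus each cell's
full mask, so overlap pixels stay recoverable.

**Measurements.** Mean cell intensity (cells weighted equally) and the summed
mean difference SMD = (1/N_C) Σ_c (1/N_c) Σ_p |I(p) − A_c|, the per-cell mean
absolute deviation from the cell's own mean.

**Segmentation harness.** The conventional pipeline — DoG band-pass, k-means
figure-ground, marker-based watershed on w·edge + (1−w)·(1−dist), minimum
area a_min — scored by the combined Jaccard (greedy one-to-one matching,
normalized by max(n_pred, n_gt)), tuned by cyclic coordinate descent and
validated by seeded k-fold cross-validation.

## Worked example

`examples/04_metrics.py` trains a shape model on 12 procedural blob patches,
simulates the four-degree overlap series (4 images each, everything but the
overlap held constant) and measures both statistics:

```
                     isolated  touching  overlapping  overlaying
mean_cell_intensity     81.26     81.23       110.35      172.67
smd                     21.07     21.06        33.62       59.39
```

Mean in-cell intensity rises with overlap because fluorescence is additive
where cells stack; the two zero-overlap degrees agree to within rounding.
`examples/05_segmentation_benchmark.py` then runs the reference pipeline with
3-fold cross-validation on the same kind of series:

```
  isolated     0.677
  touching     0.656
  overlapping  0.377
  overlaying   0.223
```

The combined Jaccard falls as overlap grows — the watershed can split
touching cells but cannot resolve genuinely overlapping ones.

The other examples cover shape-model training (`01`), the texture-warp
dilation oracle (`02`, mean deviation 0.51 px ≈ 2.8 % of the target radius)
and dataset simulation with ground-truth round trip (`03`).

A `fluocell` console script exposes the same pipeline from the shell
(`make-fixtures`, `train-model`, `simulate`, `overlap-series`, `measure`,
`evaluate`); run `fluocell --help`.

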