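"""Train a PCA shape model on procedural cell outlines and sample new shapes.

The model decomposes aligned, corresponded contours into a mean shape and
orthonormal variation modes; new outlines are the mean plus a random
combination of modes, rejected if they fall below the minimum size r_min.
"""

import numpy as np

import fluocell as fc

patches = fc.generate_patches(fc.FixtureSpec(
    cell_kind="blob", n_patches=50, rng_seed=1, n_points=64,
    radius_range=(10, 16)))
vectors = fc.normalize_and_correspond([p.contour for p in patches])
model = fc.fit_shape_model(vectors, n_modes=8, r_min=8.0)

print("eigenvalues (px^2):", np.round(model.eigenvalues, 2))
explained = model.eigenvalues / model.eigenvalues.sum()
print(f"first mode explains {explained[0]:.0%} of the contour variance "
      "(mostly overall size)")

rng = np.random.default_rng(2)
radii = [fc.generate_shape(model, rng).contour.mean_radius() for _ in range(500)]
train_radii = [p.contour.mean_radius() for p in patches]
print(f"mean radius: training {np.mean(train_radii):.2f} px, "
      f"generated {np.mean(radii):.2f} px (should agree closely)")
print(f"smallest generated radius {min(radii):.2f} px >= r_min {model.r_min} px")
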