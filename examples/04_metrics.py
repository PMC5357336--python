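"""Objective measurements over an overlap series.

Simulates the four overlap degrees (isolated, touching, overlapping,
overlaying) with all other parameters held constant, then measures mean cell
intensity and SMD edge strength per degree.  With additive composition the
in-cell intensity must rise with overlap; SMD rises too because background
cells are not blurred in the overlap regions.
"""

import fluocell as fc
from fluocell.placement import LayoutSpec
from fluocell.scene import PerlinParams

patches = fc.generate_patches(fc.FixtureSpec(
    n_patches=12, rng_seed=1, n_points=64, radius_range=(9, 13)))
vectors = fc.normalize_and_correspond([p.contour for p in patches])
model = fc.fit_shape_model(vectors, n_modes=8, r_min=5.0)

config = fc.SceneConfig(
    layout=LayoutSpec(n_cells=5, image_size=(128, 128)),
    background=PerlinParams(octaves=2, base_frequency=1 / 48,
                            amplitude=8.0, offset=5.0),
    gaussian_noise_sigma=2.0,
    n_images=4, n_points=64, rng_seed=7,
)
series = fc.simulate_overlap_series(model, patches, config)
table = fc.overlap_series_table(series)
print(table.round(2))
print("\nmean cell intensity rises with overlap (fluorescence is additive "
      "where cells stack); SMD rises because overlap edges add texture.")
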