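"""Shared fixtures: procedural patch pools, trained shape models, disk scenes."""

import numpy as np
import pytest

import fluocell as fc


def disk_mask(r: int) -> np.ndarray:
    yy, xx = np.mgrid[0: 2 * r + 3, 0: 2 * r + 3]
    return (xx - r - 1) ** 2 + (yy - r - 1) ** 2 <= r * r


def circle_mask(radius: float, size: int = 64) -> np.ndarray:
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def patch_pool():
    """Twelve blob patches with radial-gradient texture, 64 contour points."""
    return fc.generate_patches(fc.FixtureSpec(
        n_patches=12, rng_seed=1, n_points=64, radius_range=(9, 13),
        texture_kind="radial-gradient",
    ))


@pytest.fixture(scope="session")
def shape_model(patch_pool):
    vecs = fc.normalize_and_correspond([p.contour for p in patch_pool])
    return fc.fit_shape_model(vecs, n_modes=8, r_min=5.0)


@pytest.fixture(scope="session")
def disk_patch():
    """Uniform-intensity disk patch (radius 12) with its sampled contour."""
    yy, xx = np.mgrid[0:30, 0:30]
    mask = (xx - 14.5) ** 2 + (yy - 14.5) ** 2 <= 12**2
    contour = fc.sample_contour(mask, 64)
    return fc.TexturePatch(np.where(mask, 100.0, 0.0), mask, contour,
                           source_id="disk-uniform")


@pytest.fixture(scope="session")
def gradient_disk_patch():
    """Radial-gradient disk patch: intensity falls from 150 to 30 at the rim."""
    yy, xx = np.mgrid[0:30, 0:30]
    r = np.hypot(xx - 14.5, yy - 14.5)
    mask = r <= 12
    inten = np.where(mask, 150.0 * (1.0 - 0.8 * r / 12.0), 0.0)
    contour = fc.sample_contour(mask, 64)
    return fc.TexturePatch(inten, mask, contour, source_id="disk-gradient")


@pytest.fixture(scope="session")
def tiny_scene_config():
    """Deterministic composition: flat background, no noise."""
    return fc.SceneConfig(
        layout=fc.LayoutSpec(n_cells=5, n_clusters=1, image_size=(128, 128)),
        background=fc.PerlinParams(amplitude=0.0, offset=8.0),
        gaussian_noise_sigma=0.0,
        n_images=2, n_points=64, rng_seed=7,
    )


def disk_scene(centers, r, shape=(96, 96), val=150.0, bg=10.0, noise=3.0, seed=0):
    """Synthetic micrograph of uniform disks with known masks."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, bg)
    masks = []
    for cx, cy in centers:
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img += np.where(m, val, 0.0)
        masks.append(m)
    if noise > 0:
        img = img + rng.normal(0, noise, shape)
    return np.clip(img, 0, 255), masks
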