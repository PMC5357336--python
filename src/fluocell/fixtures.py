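"""Procedural texture patches.

Real training data for the simulator consists of hand-annotated cell patches
(an intensity raster plus a binary mask per cell).  This module generates
stand-in patches procedurally — disks, ellipses and band-limited "blob"
polygons carrying uniform, radial-gradient or speckle textures — so that the
shape model, the texture warp and the full scene pipeline can be exercised
end-to-end without any external data.  Every generated patch satisfies the
same invariants as an annotated one (single connected mask component, simple
boundary polygon, zero intensity outside the mask) and is validated by the
shared :func:`validate_patch` check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .shape_model import Contour, sample_contour
from .texture import TexturePatch

__all__ = ["FixtureSpec", "generate_patches", "blob_polygon", "validate_patch"]

CELL_KINDS = ("disk", "ellipse", "blob")
TEXTURE_KINDS = ("uniform", "radial-gradient", "speckle")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a batch of procedural cell patches."""

    cell_kind: str = "blob"
    texture_kind: str = "radial-gradient"
    radius_range: tuple[float, float] = (10.0, 16.0)
    intensity_range: tuple[float, float] = (80.0, 180.0)
    n_patches: int = 10
    n_points: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_kind not in CELL_KINDS:
            raise ValueError(f"cell_kind must be one of {CELL_KINDS}")
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(f"texture_kind must be one of {TEXTURE_KINDS}")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius range must be positive")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")


def blob_polygon(rng: np.random.Generator, radius: float, n_vertices: int = 180,
                 max_harmonic: int = 6, amplitude: float = 0.18) -> np.ndarray:
    """Band-limited radial perturbation of a circle.

    r(theta) = R (1 + sum_k a_k cos(k theta + phi_k)), k = 2..max_harmonic,
    with sum |a_k| < 1 so the polygon stays star-shaped, hence simple.
    """
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, max_harmonic + 1):
        a_k = rng.uniform(-amplitude, amplitude) / (k - 1)
        phi = rng.uniform(0, 2 * np.pi)
        r += a_k * np.cos(k * theta + phi)
    r = np.clip(r, 0.3, None) * radius
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _mask_from_polygon(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a polygon into a tight binary mask; returns (mask, shifted poly)."""
    margin = 2.0
    shift = margin - poly.min(axis=0)
    poly = poly + shift
    h = int(np.ceil(poly[:, 1].max() + margin)) + 1
    w = int(np.ceil(poly[:, 0].max() + margin)) + 1
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask, poly


def _texture(rng: np.random.Generator, mask: np.ndarray, kind: str,
             lo: float, hi: float) -> np.ndarray:
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    peak = rng.uniform(max(lo, 0.6 * hi), hi)
    if kind == "uniform":
        img = np.full((h, w), peak)
    elif kind == "radial-gradient":
        r = np.hypot(xx - cx, yy - cy)
        r_max = r[mask].max()
        img = peak * (1.0 - 0.85 * r / max(r_max, 1e-9))
    else:  # speckle: bright Gaussian granules on a dim plasma base
        base = 0.25 * peak
        img = np.full((h, w), base)
        n_granules = max(3, int(mask.sum() / 60))
        idx = rng.choice(len(ys), size=n_granules, replace=True)
        for gy, gx in zip(ys[idx], xs[idx]):
            sig = rng.uniform(1.0, 2.5)
            amp = rng.uniform(0.4, 1.0) * (peak - base)
            img += amp * np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * sig**2))
    img = np.clip(img, 0.0, 255.0)
    img[~mask] = 0.0
    return img


def generate_patches(spec: FixtureSpec) -> list[TexturePatch]:
    """Generate ``spec.n_patches`` seeded-deterministic procedural patches."""
    rng = np.random.default_rng(spec.rng_seed)
    patches = []
    for i in range(spec.n_patches):
        radius = rng.uniform(*spec.radius_range)
        if spec.cell_kind == "disk":
            poly = blob_polygon(rng, radius, amplitude=0.0)
        elif spec.cell_kind == "ellipse":
            ecc = rng.uniform(0.5, 0.95)
            theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
            pts = np.column_stack([radius * np.cos(theta), ecc * radius * np.sin(theta)])
            ang = rng.uniform(0, np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            poly = pts @ rot.T
        else:
            poly = blob_polygon(rng, radius)
        mask, _ = _mask_from_polygon(poly)
        intensity = _texture(rng, mask, spec.texture_kind,
                             spec.intensity_range[0], spec.intensity_range[1])
        contour = sample_contour(mask, spec.n_points)
        patch = TexturePatch(
            intensity=intensity, mask=mask, contour=contour,
            source_id=f"fixture:{spec.cell_kind}:{spec.texture_kind}:{spec.rng_seed}:{i}",
        )
        validate_patch(patch)
        patches.append(patch)
    return patches


def validate_patch(patch: TexturePatch) -> None:
    """Invariant suite shared by procedural fixtures and annotated input patches."""
    if patch.intensity.shape != patch.mask.shape:
        raise ValueError("intensity and mask extents differ")
    if patch.intensity.min() < 0 or patch.intensity.max() > 255:
        raise ValueError("intensity must lie in [0, 255]")
    if np.any(patch.intensity[~patch.mask] != 0):
        raise ValueError("intensity outside the mask must be 0")
    _, n_comp = measure.label(patch.mask, return_num=True, connectivity=2)
    if n_comp != 1:
        raise ValueError("mask must be a single connected component")
    if not patch.contour.is_simple():
        raise ValueError("boundary polygon self-intersects")
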