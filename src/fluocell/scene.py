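"""Scene composition: full synthetic micrographs with pixel-exact ground truth.

A scene is built in the pipeline order background -> cells -> noise: a Perlin
gradient-noise background emulating smooth fluorescence artifacts, the warped
cells added at their placed offsets (overlapping regions are additive, as
fluorescence intensities of stacked cells are), and finally pixel-wise
Gaussian noise.  The result is clipped to the bit depth.  Every scene carries
its own ground truth: an instance label map (topmost cell per pixel) plus the
complete per-cell masks, so overlapping pixels remain recoverable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .placement import (LayoutSpec, Placement, place_cells, spec_for_degree,
                        OVERLAP_DEGREES)
from .shape_model import Contour, ShapeModel, generate_shape
from .texture import RenderedCell, WarpWeights, select_patch, warp_texture

__all__ = [
    "PerlinParams",
    "SceneConfig",
    "CellTruth",
    "SimulatedScene",
    "perlin_background",
    "compose_scene",
    "simulate_scene",
    "simulate_dataset",
    "simulate_overlap_series",
]


@dataclass(frozen=True)
class PerlinParams:
    """Octave-summed gradient noise: min-max scaled to [offset, offset+amplitude]."""

    octaves: int = 3
    base_frequency: float = 1 / 64        # lattice cells per pixel at octave 0
    amplitude: float = 20.0
    offset: float = 10.0

    def __post_init__(self) -> None:
        if self.octaves < 1 or self.base_frequency <= 0 or self.amplitude < 0:
            raise ValueError("invalid Perlin parameters")


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to simulate one dataset of scenes."""

    layout: LayoutSpec
    background: PerlinParams = field(default_factory=PerlinParams)
    gaussian_noise_sigma: float = 3.0
    bit_depth: int = 8
    composition_mode: str = "additive"     # or "maximum"
    n_images: int = 30
    n_points: int = 64                     # contour points per cell
    warp_weights: WarpWeights = field(default_factory=WarpWeights)
    fixation_stride: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.composition_mode not in ("additive", "maximum"):
            raise ValueError("composition_mode must be 'additive' or 'maximum'")
        if self.gaussian_noise_sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class CellTruth:
    """Per-cell ground truth: full mask (recoverable under overlaps)."""

    mask: np.ndarray               # bounding-box binary mask
    offset: tuple[int, int]        # (x, y) of the mask origin in the scene
    polygon: np.ndarray            # contour points in scene coordinates
    cluster_id: int
    source_patch_id: str

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        x0, y0 = self.offset
        h, w = self.mask.shape
        out[y0: y0 + h, x0: x0 + w] = self.mask
        return out


@dataclass
class SimulatedScene:
    image: np.ndarray              # clipped integer raster
    label_map: np.ndarray          # 0 = background, k = cell k (topmost wins)
    cells: list[CellTruth]
    config: SceneConfig
    rng_seed: int                  # per-scene sub-seed
    clipped_fraction: float = 0.0

    def cell_masks(self) -> list[np.ndarray]:
        return [c.full_mask(self.image.shape) for c in self.cells]


def _perlin_octave(size, freq, rng):
    """Single octave of 2-D gradient (Perlin) noise on a [0, 1]-ish scale."""
    w, h = size
    nx = int(np.ceil(w * freq)) + 1
    ny = int(np.ceil(h * freq)) + 1
    ang = rng.uniform(0, 2 * np.pi, (ny + 1, nx + 1))
    grad = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    x = np.arange(w) * freq
    y = np.arange(h) * freq
    xi = x.astype(int)
    yi = y.astype(int)
    xf = x - xi
    yf = y - yi
    u = xf * xf * xf * (xf * (xf * 6 - 15) + 10)     # smoothstep fade
    v = yf * yf * yf * (yf * (yf * 6 - 15) + 10)
    xf2, yf2 = np.meshgrid(xf, yf)
    u2, v2 = np.meshgrid(u, v)
    out = np.zeros((h, w))
    n = {}
    for dy in (0, 1):
        for dx in (0, 1):
            g = grad[yi[:, None] + dy, xi[None, :] + dx]
            n[(dy, dx)] = g[..., 0] * (xf2 - dx) + g[..., 1] * (yf2 - dy)
    nx0 = n[(0, 0)] + u2 * (n[(0, 1)] - n[(0, 0)])
    nx1 = n[(1, 0)] + u2 * (n[(1, 1)] - n[(1, 0)])
    return nx0 + v2 * (nx1 - nx0)


def perlin_background(size, params: PerlinParams, seed: int = 0) -> np.ndarray:
    """Octave-summed gradient noise scaled to [offset, offset + amplitude].

    ``size`` is (width, height); per-octave amplitude halves while frequency
    doubles.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    w, h = size
    total = np.zeros((h, w))
    amp = 1.0
    freq = params.base_frequency
    for _ in range(params.octaves):
        total += amp * _perlin_octave(size, freq, rng)
        amp *= 0.5
        freq *= 2.0
    if params.amplitude == 0:
        return np.full((h, w), float(params.offset))
    lo, hi = total.min(), total.max()
    if hi - lo < 1e-12:
        return np.full((h, w), params.offset + 0.5 * params.amplitude)
    return params.offset + params.amplitude * (total - lo) / (hi - lo)


def compose_scene(
    cells: list[RenderedCell],
    placement: Placement,
    config: SceneConfig,
    seed: int | None = None,
) -> SimulatedScene:
    """Compose rendered cells, background and noise into one scene.

    image = clip(background + sum of cell intensities (additive mode)
                 + N(0, sigma), 0, 2^bit_depth - 1).
    """
    if len(cells) != len(placement.cells):
        raise ValueError("placement inconsistent with cell list")
    seed = placement.spec.rng_seed if seed is None else seed
    w, h = placement.spec.image_size
    rng = np.random.default_rng(seed)
    bg = perlin_background((w, h), config.background, seed=seed)

    layer = np.zeros((h, w))
    label_map = np.zeros((h, w), dtype=np.int32)
    truths: list[CellTruth] = []
    for k, cp in enumerate(placement.cells, start=1):
        rc = cells[cp.cell_index]
        x0, y0 = cp.offset
        mh, mw = rc.mask.shape
        if x0 < 0 or y0 < 0 or x0 + mw > w or y0 + mh > h:
            raise ValueError(f"cell {cp.cell_index} outside image bounds")
        region = (slice(y0, y0 + mh), slice(x0, x0 + mw))
        if config.composition_mode == "additive":
            layer[region] += rc.intensity
        else:
            layer[region] = np.maximum(layer[region], rc.intensity)
        label_map[region][rc.mask] = k            # topmost cell wins
        poly = rc.poly_scene if hasattr(rc, "poly_scene") else None
        truths.append(CellTruth(
            mask=rc.mask.copy(),
            offset=(x0, y0),
            polygon=poly if poly is not None else np.zeros((0, 2)),
            cluster_id=cp.cluster_index,
            source_patch_id=rc.source_id,
        ))

    raw = bg + layer
    if config.gaussian_noise_sigma > 0:
        raw = raw + rng.normal(0.0, config.gaussian_noise_sigma, raw.shape)
    clipped = np.clip(raw, 0, config.max_value)
    clipped_fraction = float(np.mean(raw != clipped))
    if clipped_fraction > 0.01:
        warnings.warn(f"{clipped_fraction:.1%} of pixels clipped", stacklevel=2)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    image = np.rint(clipped).astype(dtype)
    return SimulatedScene(
        image=image, label_map=label_map, cells=truths, config=config,
        rng_seed=seed, clipped_fraction=clipped_fraction,
    )


def _render_cells(model, patches, config, rng):
    """Generate shapes and warp textures for one scene's cells."""
    rendered = []
    for _ in range(config.layout.n_cells):
        sample = generate_shape(model, rng)
        target = sample.contour
        patch = select_patch(patches, target.area(), rng)
        rc = warp_texture(
            patch, target, config.warp_weights,
            fixation_stride=config.fixation_stride,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        # contour in the cell's local (bounding-box) frame for ground truth
        rc.poly_scene = target.points - np.array(rc.offset)
        rendered.append(rc)
    return rendered


def simulate_scene(model: ShapeModel, patches, config: SceneConfig, seed: int) -> SimulatedScene:
    """Simulate one scene: shapes -> textures -> placement -> composition."""
    rng = np.random.default_rng(seed)
    rendered = _render_cells(model, patches, config, rng)
    layout = replace(config.layout, rng_seed=int(rng.integers(2**31 - 1)))
    placement = place_cells([rc.mask for rc in rendered], layout)
    scene = compose_scene(rendered, placement, config, seed=int(rng.integers(2**31 - 1)))
    scene.rng_seed = seed
    # translate per-cell polygons into scene coordinates
    for truth in scene.cells:
        truth.polygon = truth.polygon + np.array(truth.offset, dtype=float)
    return scene


def _child_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_dataset(
    model: ShapeModel, patches, config: SceneConfig
) -> tuple[list[SimulatedScene], dict]:
    """Simulate ``config.n_images`` scenes from independent per-image sub-seeds.

    Returns the scenes and a manifest recording every sub-seed.
    """
    seeds = _child_seeds(config.rng_seed, config.n_images)
    scenes = [simulate_scene(model, patches, config, s) for s in seeds]
    manifest = {
        "master_seed": config.rng_seed,
        "n_images": config.n_images,
        "entries": [{"index": i, "seed": s} for i, s in enumerate(seeds)],
    }
    return scenes, manifest


def simulate_overlap_series(
    model: ShapeModel, patches, config: SceneConfig,
    degrees=OVERLAP_DEGREES,
) -> dict[str, list[SimulatedScene]]:
    """One dataset per overlap degree, all other parameters held constant.

    Per-image sub-seeds are shared across degrees, so each degree draws the
    same cells, textures and background and differs only in placement.
    """
    seeds = _child_seeds(config.rng_seed, config.n_images)
    out = {}
    for degree in degrees:
        cfg = replace(config, layout=spec_for_degree(config.layout, degree))
        out[degree] = [simulate_scene(model, patches, cfg, s) for s in seeds]
    return out
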