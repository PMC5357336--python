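"""Clustered cell placement under a pairwise-overlap bound.

Cells are assigned to ``n_clusters`` clusters whose centers are drawn
uniformly inside the image (with a margin so cells fit).  The first cell of a
cluster sits at the cluster center; every further cell starts at the center
and is moved outward in ``step``-pixel increments along a random direction
until its maximum Jaccard overlap with the already placed cells drops to the
bound ``j_max``.  The overlap is checked against *all* previously placed
cells in the scene, so the bound is global; the emitted ground-truth masks
can always be re-audited with :func:`jaccard`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation

__all__ = [
    "LayoutSpec",
    "CellPlacement",
    "Placement",
    "jaccard",
    "place_cells",
    "overlap_presets",
    "OVERLAP_DEGREES",
]

OVERLAP_DEGREES = ("isolated", "touching", "overlapping", "overlaying")

# j_max per overlap degree; "isolated" additionally keeps a 2 px minimum gap
_PRESETS = {
    "isolated": {"n_clusters": 1, "j_max": 0.0, "min_gap": 2},
    "touching": {"n_clusters": 1, "j_max": 0.0, "min_gap": 0},
    "overlapping": {"n_clusters": 1, "j_max": 0.15, "min_gap": 0},
    "overlaying": {"n_clusters": 1, "j_max": 0.40, "min_gap": 0},
}


@dataclass(frozen=True)
class LayoutSpec:
    """Placement parameters: cell/cluster counts, overlap bound, geometry."""

    n_cells: int
    n_clusters: int = 1
    j_max: float = 0.0
    image_size: tuple[int, int] = (256, 256)   # (width, height)
    step: float = 1.0
    min_gap: int = 0                            # minimum background gap, px
    strict: bool = False                        # strictly-below-j_max mode
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_clusters <= self.n_cells):
            raise ValueError("need 1 <= n_clusters <= n_cells")
        if not (0.0 <= self.j_max <= 1.0):
            raise ValueError("j_max must be in [0, 1]")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass(frozen=True)
class CellPlacement:
    cell_index: int
    cluster_index: int
    offset: tuple[int, int]        # top-left (x, y) of the cell mask in the scene
    max_overlap: float             # realized max Jaccard against earlier cells


@dataclass
class Placement:
    cells: list[CellPlacement]
    spec: LayoutSpec
    cluster_centers: np.ndarray    # (n_clusters, 2) in (x, y)

    def pairwise_overlaps(self, masks) -> np.ndarray:
        """Recompute every pairwise Jaccard from the placed masks (audit)."""
        n = len(self.cells)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = _jaccard_at(
                    masks[i], self.cells[i].offset, masks[j], self.cells[j].offset
                )
        return out


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| of two masks on a common frame."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a coordinate frame")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


def _jaccard_at(mask_a, off_a, mask_b, off_b) -> float:
    """Jaccard of two bounding-box masks positioned at integer offsets."""
    ax, ay = off_a
    bx, by = off_b
    ah, aw = mask_a.shape
    bh, bw = mask_b.shape
    x0, x1 = max(ax, bx), min(ax + aw, bx + bw)
    y0, y1 = max(ay, by), min(ay + ah, by + bh)
    if x0 >= x1 or y0 >= y1:
        inter = 0
    else:
        sub_a = mask_a[y0 - ay: y1 - ay, x0 - ax: x1 - ax]
        sub_b = mask_b[y0 - by: y1 - by, x0 - bx: x1 - bx]
        inter = int(np.logical_and(sub_a, sub_b).sum())
    union = int(mask_a.sum()) + int(mask_b.sum()) - inter
    return inter / union if union else 0.0


def _gap_violation(mask_a, off_a, mask_b, off_b, gap: int) -> bool:
    """True when mask_b comes within ``gap`` pixels of mask_a."""
    if gap <= 0:
        return False
    grown = binary_dilation(np.pad(mask_a, gap), iterations=gap)
    return _jaccard_at(grown, (off_a[0] - gap, off_a[1] - gap), mask_b, off_b) > 0


def overlap_presets(degree: str) -> dict:
    """LayoutSpec fragment (n_clusters, j_max, min_gap) for an overlap degree.

    The four degrees span isolated (disjoint with a 2 px gap), touching
    (masks may abut), overlapping (j_max 0.15) and overlaying (j_max 0.40).
    """
    if degree not in _PRESETS:
        raise ValueError(f"unknown overlap degree {degree!r}; expected one of {OVERLAP_DEGREES}")
    return dict(_PRESETS[degree])


def place_cells(masks, spec: LayoutSpec, max_direction_retries: int = 32) -> Placement:
    """Place cell masks in the scene respecting the overlap bound.

    ``masks`` are per-cell binary bounding-box rasters.  Deterministic for a
    fixed ``spec.rng_seed``; raises "layout infeasible" when a cell cannot be
    positioned fully inside the image within the retry budget.
    """
    if not masks:
        raise ValueError("need at least one mask")
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if any(not m.any() for m in masks):
        raise ValueError("empty cell mask")
    w, h = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)

    # margin: largest cell "radius" (half bounding-box diagonal)
    radius = max(0.5 * np.hypot(*m.shape) for m in masks)
    margin = min(radius, min(w, h) / 2 - 1)
    centers = np.column_stack([
        rng.uniform(margin, w - margin, spec.n_clusters),
        rng.uniform(margin, h - margin, spec.n_clusters),
    ])

    # balanced random assignment: cluster sizes differ by at most one, order
    # random; with n_clusters == n_cells every cell gets its own cluster
    clusters = rng.permutation(np.resize(np.arange(spec.n_clusters), len(masks)))
    first_in_cluster = np.ones(spec.n_clusters, dtype=bool)
    placed: list[CellPlacement] = []

    def offset_for(mask, center_xy):
        mh, mw = mask.shape
        return (int(round(center_xy[0] - mw / 2)), int(round(center_xy[1] - mh / 2)))

    def inside(mask, off):
        mh, mw = mask.shape
        return 0 <= off[0] and 0 <= off[1] and off[0] + mw <= w and off[1] + mh <= h

    def ok(mask, off):
        worst = 0.0
        for prev in placed:
            j = _jaccard_at(masks[prev.cell_index], prev.offset, mask, off)
            worst = max(worst, j)
            exceeded = j >= spec.j_max if spec.strict and spec.j_max > 0 else j > spec.j_max
            if exceeded:
                return False, worst
            if spec.min_gap > 0 and _gap_violation(
                masks[prev.cell_index], prev.offset, mask, off, spec.min_gap
            ):
                return False, worst
        return True, worst

    for ci, mask in enumerate(masks):
        k = int(clusters[ci])
        center = centers[k]
        if first_in_cluster[k]:
            off = offset_for(mask, center)
            if not inside(mask, off):
                raise RuntimeError("layout infeasible: cluster center does not fit the cell")
            good, worst = ok(mask, off)
            if not good:
                first_in_cluster[k] = False   # treat like a later cell below
            else:
                placed.append(CellPlacement(ci, k, off, worst))
                first_in_cluster[k] = False
                continue
        success = False
        for _ in range(max_direction_retries):
            theta = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(theta), np.sin(theta)])
            t = 0.0
            while True:
                pos = center + t * direction
                off = offset_for(mask, pos)
                if not inside(mask, off):
                    break                      # left the image: new direction
                good, worst = ok(mask, off)
                if good:
                    placed.append(CellPlacement(ci, k, off, worst))
                    success = True
                    break
                t += spec.step
            if success:
                break
        if not success:
            raise RuntimeError(
                f"layout infeasible: cell {ci} cannot satisfy j_max={spec.j_max} "
                f"within {max_direction_retries} directions"
            )
    return Placement(cells=placed, spec=spec, cluster_centers=centers)


def spec_for_degree(base: LayoutSpec, degree: str) -> LayoutSpec:
    """Apply an overlap-degree preset to a base layout spec."""
    return replace(base, **overlap_presets(degree))
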