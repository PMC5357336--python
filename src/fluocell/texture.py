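"""Elastic texture warping.

Maps the texture of an annotated reference cell onto a newly generated cell
shape.  The texture is treated as an elastic tissue spanned between fixation
points: every mask pixel becomes a movable point, and three weighted elastic
energies govern the motion,

    E = w_fix E_fix(v_fix) + w_border E_border(v_border) + w_bulk E_bulk(v_bulk)

* ``E_fix``    — zero-rest-length springs between fixation points (a subset of
  the boundary) and their corresponding points on the target contour;
* ``E_border`` — zero-rest-length springs between adjacent boundary points;
* ``E_bulk``   — springs between 8-connected interior points whose stiffness
  grows with local intensity: each edge carries the constant
  ``log(1+I(p)) * log(1+I(n))``, so bright regions are stiff and resist
  distortion while dim regions stretch.

:func:`bulk_force` evaluates the per-point gradient of ``E_bulk``,
``sum_n log(1+I(p)) log(1+I(n)) (p - n)``; the relaxation in :func:`relax` is
gradient descent, i.e. every point is stepped along the *negative* of that
gradient (toward its neighbours) together with the fix/border spring restoring
forces.  Points are processed sequentially in a seeded random order and each
move is capped at ``step_cap`` pixels; total energy is non-increasing until
convergence.  After convergence the warped points are splatted back to the
pixel grid and holes inside the target mask are filled by inverse-distance
interpolation (:func:`rasterize`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon

from .shape_model import Contour

__all__ = [
    "TexturePatch",
    "WarpWeights",
    "PointSystem",
    "RenderedCell",
    "init_point_system",
    "bulk_force",
    "spring_forces",
    "relax",
    "rasterize",
    "warp_texture",
    "select_patch",
]


@dataclass
class TexturePatch:
    """One annotated (or procedural) cell: intensity + mask + sampled contour."""

    intensity: np.ndarray
    mask: np.ndarray
    contour: Contour
    source_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask extents differ")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class WarpWeights:
    """Non-negative weights of the three elastic energy terms."""

    w_fix: float = 10.0
    w_border: float = 1.0
    w_bulk: float = 0.08

    def __post_init__(self) -> None:
        if min(self.w_fix, self.w_border, self.w_bulk) < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class PointSystem:
    """Warping state: point positions, classes, neighbour graphs and weights.

    Point order: fixation points (sub-pixel contour points, indices
    0..n_fix-1), then boundary pixels (together the border class,
    0..n_border-1), then interior (bulk) pixels.  ``fix_slot[i] >= 0`` pairs
    fixation point ``i`` with ``fix_targets[fix_slot[i]]`` on the target
    contour.  Neighbour graphs are stored CSR-style; ``bulk_k`` holds the
    per-edge intensity stiffness ``log(1+I(p)) log(1+I(n))``.
    """

    positions: np.ndarray          # (M, 2) current point positions, (x, y)
    source_pixels: np.ndarray      # (M, 2) integer (x, y) pixel of origin in the patch
    intensities: np.ndarray        # (M,) source intensity per point
    n_fix: int                     # fixation (contour) points, indices [0, n_fix)
    n_border: int                  # fixation + boundary-pixel points, [0, n_border)
    fix_slot: np.ndarray           # (M,) int, -1 = not a fixation point
    fix_targets: np.ndarray        # (n_fix, 2) target positions
    border_indptr: np.ndarray
    border_indices: np.ndarray
    bulk_indptr: np.ndarray
    bulk_indices: np.ndarray
    bulk_k: np.ndarray             # stiffness per entry of bulk_indices
    weights: WarpWeights = field(default_factory=WarpWeights)
    energy_trace: np.ndarray | None = None      # total energy per sweep (set by relax)
    energy_trace_fb: np.ndarray | None = None   # fix+border energy per sweep

    @property
    def n_points(self) -> int:
        return int(self.positions.shape[0])

    @property
    def is_border(self) -> np.ndarray:
        out = np.zeros(self.n_points, dtype=bool)
        out[: self.n_border] = True
        return out

    def energy_parts(self) -> tuple[float, float]:
        """(fix+border, bulk) weighted elastic energies at current positions."""
        w = self.weights
        fixed = self.fix_slot >= 0
        e_fb = 0.0
        if fixed.any():
            d = self.fix_targets[self.fix_slot[fixed]] - self.positions[fixed]
            e_fb += w.w_fix * 0.5 * float(np.sum(d**2))
        parts = []
        for indptr, indices, ks, wt in (
            (self.border_indptr, self.border_indices, None, w.w_border),
            (self.bulk_indptr, self.bulk_indices, self.bulk_k, w.w_bulk),
        ):
            i = np.repeat(np.arange(self.n_points), np.diff(indptr))
            j = indices
            d2 = np.sum((self.positions[i] - self.positions[j]) ** 2, axis=1)
            k = ks if ks is not None else np.ones_like(d2)
            # each undirected spring appears twice in CSR -> halve again
            parts.append(wt * 0.25 * float(np.sum(k * d2)))
        return e_fb + parts[0], parts[1]

    def energy(self) -> float:
        """Total weighted elastic energy at the current positions."""
        return sum(self.energy_parts())


@dataclass
class RenderedCell:
    """A warped cell rasterized into the target shape's bounding box."""

    intensity: np.ndarray
    mask: np.ndarray
    offset: tuple[int, int]        # raster origin (x, y) in target coordinates
    source_id: str = ""


def _rigid_align(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation taking src points onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = (u @ np.diag([1.0, d]) @ vt).T
    t = cd - r @ cs
    return r, t


def _csr_from_edges(n: int, edges: np.ndarray, values: np.ndarray | None = None):
    """Symmetric CSR adjacency from an (E, 2) undirected edge list."""
    if len(edges) == 0:
        indptr = np.zeros(n + 1, dtype=np.int64)
        return indptr, np.zeros(0, dtype=np.int64), np.zeros(0)
    both = np.vstack([edges, edges[:, ::-1]])
    vals = np.ones(len(both)) if values is None else np.concatenate([values, values])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both, vals = both[order], vals[order]
    counts = np.bincount(both[:, 0], minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, both[:, 1].astype(np.int64), vals


def init_point_system(
    patch: TexturePatch,
    target: Contour,
    weights: WarpWeights | None = None,
    fixation_stride: int = 4,
) -> PointSystem:
    """Build the warping state for mapping ``patch`` onto ``target``.

    The patch contour is rigidly aligned (rotation + translation, least
    squares) to the target contour.  Every ``fixation_stride``-th contour
    point becomes a fixation point, paired with the same-index target contour
    point and linked by border springs to its two nearest boundary pixels.
    Boundary pixels of the mask are border points, interior pixels are bulk
    points; the bulk neighbour graph links 8-adjacent mask pixels.
    """
    weights = weights or WarpWeights()
    if patch.contour.n_points != target.n_points:
        raise ValueError("patch contour and target must have the same point count")
    if not patch.mask.any():
        raise ValueError("empty mask")

    r, t = _rigid_align(patch.contour.points, target.points)

    mask = patch.mask
    eroded = binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    border_mask = mask & ~eroded
    if not border_mask.any():        # patch too thin to have an interior
        border_mask = mask
    sel = np.arange(0, target.n_points, fixation_stride)
    n_fix = len(sel)
    fix_src = patch.contour.points[sel]                       # sub-pixel positions
    ys_b, xs_b = np.nonzero(border_mask)
    ys_i, xs_i = np.nonzero(mask & ~border_mask)
    px_src = np.column_stack(
        [np.concatenate([xs_b, xs_i]), np.concatenate([ys_b, ys_i])]
    ).astype(np.int64)
    n_border_px = len(xs_b)
    n_border = n_fix + n_border_px
    m = n_fix + len(px_src)
    src_pos = np.vstack([fix_src, px_src.astype(float)])
    positions = src_pos @ r.T + t
    # fixation points sample the intensity of their nearest boundary pixel
    # (the nearest raster pixel can fall outside the mask)
    border_px = px_src[:n_border_px]
    fix_px = np.empty((n_fix, 2), dtype=np.int64)
    for slot in range(n_fix):
        d = np.linalg.norm(border_px.astype(float) - fix_src[slot], axis=1)
        fix_px[slot] = border_px[int(np.argmin(d))]
    source_pixels = np.vstack([fix_px, px_src])
    intensities = patch.intensity[source_pixels[:, 1], source_pixels[:, 0]].astype(float)
    if intensities.min() < 0:
        raise ValueError("negative intensity")

    # map pixel -> point index for adjacency construction (pixels come after fix)
    index_map = -np.ones(mask.shape, dtype=np.int64)
    index_map[px_src[:, 1], px_src[:, 0]] = n_fix + np.arange(len(px_src))

    offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    edges = []
    for dx, dy in offsets:
        x2, y2 = px_src[:, 0] + dx, px_src[:, 1] + dy
        ok = (x2 >= 0) & (x2 < mask.shape[1]) & (y2 >= 0) & (y2 < mask.shape[0])
        j = np.full(len(px_src), -1, dtype=np.int64)
        j[ok] = index_map[y2[ok], x2[ok]]
        valid = j >= 0
        i = n_fix + np.nonzero(valid)[0]
        edges.append(np.column_stack([i, j[valid]]))
    all_edges = np.vstack(edges)
    all_edges = all_edges[all_edges[:, 0] < all_edges[:, 1]]   # undirected, once

    border_edges = [all_edges[(all_edges[:, 0] < n_border) & (all_edges[:, 1] < n_border)]]
    # link each fixation point to its two nearest boundary pixels
    border_px_pos = px_src[:n_border_px].astype(float)
    for slot in range(n_fix):
        d = np.linalg.norm(border_px_pos - fix_src[slot], axis=1)
        nearest = np.argsort(d)[:2]
        border_edges.append(np.column_stack([
            np.full(len(nearest), slot, dtype=np.int64),
            n_fix + nearest.astype(np.int64),
        ]))
    border_edges = np.vstack(border_edges)
    li = np.log1p(intensities)
    bulk_vals = li[all_edges[:, 0]] * li[all_edges[:, 1]]
    b_indptr, b_indices, _ = _csr_from_edges(m, border_edges)
    k_indptr, k_indices, k_vals = _csr_from_edges(m, all_edges, bulk_vals)

    fix_slot = -np.ones(m, dtype=np.int64)
    fix_slot[:n_fix] = np.arange(n_fix)
    fix_targets = target.points[sel].copy()

    return PointSystem(
        positions=positions,
        source_pixels=source_pixels,
        intensities=intensities,
        n_fix=n_fix,
        n_border=n_border,
        fix_slot=fix_slot,
        fix_targets=fix_targets,
        border_indptr=b_indptr,
        border_indices=b_indices,
        bulk_indptr=k_indptr,
        bulk_indices=k_indices,
        bulk_k=k_vals,
        weights=weights,
    )


def bulk_force(
    p: np.ndarray,
    neighbors: np.ndarray,
    intensity_p: float,
    neighbor_intensities: np.ndarray,
) -> np.ndarray:
    """Gradient of the bulk elastic energy at point ``p``:

        sum_n log(1+I(p)) * log(1+I(n)) * (p - n)

    (natural logarithm).  The relaxation steps along the negative of this
    vector, i.e. toward the neighbours.
    """
    p = np.asarray(p, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    ints = np.atleast_1d(np.asarray(neighbor_intensities, dtype=float))
    if intensity_p < 0 or np.any(ints < 0):
        raise ValueError("negative intensity")
    k = np.log1p(intensity_p) * np.log1p(ints)
    return (k[:, None] * (p[None, :] - neighbors)).sum(axis=0)


def spring_forces(system: PointSystem) -> dict[str, np.ndarray]:
    """Linear spring restoring forces of the fix and border energy terms.

    Fix force on a fixation point: ``w_fix * (target - current)``.  Border
    force on a border point: ``w_border * sum_adjacent (neighbor - current)``.
    """
    w = system.weights
    pos = system.positions
    fixed = np.nonzero(system.fix_slot >= 0)[0]
    fix_f = w.w_fix * (system.fix_targets[system.fix_slot[fixed]] - pos[fixed])
    border_f = np.zeros((system.n_border, 2))
    for i in range(system.n_border):
        js = system.border_indices[system.border_indptr[i]: system.border_indptr[i + 1]]
        if len(js):
            border_f[i] = w.w_border * (pos[js] - pos[i]).sum(axis=0)
    return {"fix": fix_f, "fix_points": fixed, "border": border_f}


@njit(cache=True)
def _relax_kernel(pos, n_border, fix_slot, fix_targets,
                  border_indptr, border_indices,
                  bulk_indptr, bulk_indices, bulk_k,
                  w_fix, w_border, w_bulk, bulk_on_border,
                  eta, step_cap, tol, max_iters, seed, watch0):  # pragma: no cover
    np.random.seed(seed)
    m = pos.shape[0]
    energies = np.empty(max_iters)       # total weighted energy per sweep
    energies_fb = np.empty(max_iters)    # fix + border part (the Lyapunov term)
    prev_fb = 1e300
    rising = 0
    it = 0
    status = 0
    for it in range(max_iters):
        perm = np.random.permutation(m)
        max_disp = 0.0
        for ii in range(m):
            i = perm[ii]
            fx = 0.0
            fy = 0.0
            if i < n_border:
                for jj in range(border_indptr[i], border_indptr[i + 1]):
                    j = border_indices[jj]
                    fx += w_border * (pos[j, 0] - pos[i, 0])
                    fy += w_border * (pos[j, 1] - pos[i, 1])
                s = fix_slot[i]
                if s >= 0:
                    fx += w_fix * (fix_targets[s, 0] - pos[i, 0])
                    fy += w_fix * (fix_targets[s, 1] - pos[i, 1])
                if bulk_on_border:
                    for jj in range(bulk_indptr[i], bulk_indptr[i + 1]):
                        j = bulk_indices[jj]
                        k = bulk_k[jj]
                        fx += w_bulk * k * (pos[j, 0] - pos[i, 0])
                        fy += w_bulk * k * (pos[j, 1] - pos[i, 1])
            else:
                for jj in range(bulk_indptr[i], bulk_indptr[i + 1]):
                    j = bulk_indices[jj]
                    k = bulk_k[jj]
                    fx += w_bulk * k * (pos[j, 0] - pos[i, 0])
                    fy += w_bulk * k * (pos[j, 1] - pos[i, 1])
            dx = fx * eta
            dy = fy * eta
            norm = (dx * dx + dy * dy) ** 0.5
            if norm > step_cap:
                dx *= step_cap / norm
                dy *= step_cap / norm
                norm = step_cap
            pos[i, 0] += dx
            pos[i, 1] += dy
            if norm > max_disp:
                max_disp = norm
        # energies after the sweep
        e_fb = 0.0
        e_bulk = 0.0
        for i in range(m):
            s = fix_slot[i]
            if s >= 0:
                dx = fix_targets[s, 0] - pos[i, 0]
                dy = fix_targets[s, 1] - pos[i, 1]
                e_fb += w_fix * 0.5 * (dx * dx + dy * dy)
            for jj in range(border_indptr[i], border_indptr[i + 1]):
                j = border_indices[jj]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                e_fb += w_border * 0.25 * (dx * dx + dy * dy)
            for jj in range(bulk_indptr[i], bulk_indptr[i + 1]):
                j = bulk_indices[jj]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                e_bulk += w_bulk * 0.25 * bulk_k[jj] * (dx * dx + dy * dy)
        energies[it] = e_fb + e_bulk
        energies_fb[it] = e_fb
        # Divergence watch: without bulk forces on the border, the border/fix
        # subsystem descends e_fb autonomously, so a sustained e_fb rise can
        # only mean an unstable step; with them, the dynamics is full gradient
        # descent and the total energy is the Lyapunov function.
        e_watch = e_fb + e_bulk if bulk_on_border else e_fb
        if e_watch > prev_fb * (1.0 + 1e-12) + 1e-9:
            rising += 1
            if rising >= 10:
                status = 1
                break
        else:
            rising = 0
        # the watched energy is non-increasing for any stable step, so any
        # growth beyond the starting value signals oscillatory blow-up
        if e_watch > 2.0 * watch0 + 1e-6:
            status = 1
            break
        prev_fb = e_watch
        if max_disp < tol:
            break
    return pos, energies[: it + 1], energies_fb[: it + 1], status


def relax(
    system: PointSystem,
    max_iters: int = 5000,
    step_cap: float = 0.5,
    tol: float = 1e-3,
    eta: float = 0.05,
    rng_seed: int = 0,
    snap_distance: float = 3.0,
    bulk_on_border: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-descent relaxation of the point system.

    Each sweep processes all points in a seeded random order; every point is
    moved ``min(|f| * eta, step_cap)`` along its summed force.  Iteration stops
    when the largest per-sweep displacement drops below ``tol`` or after
    ``max_iters`` sweeps.  Fixation points ending within ``snap_distance`` of
    their target are snapped onto it exactly.  Returns the final positions and
    the per-sweep total-energy trace.

    Divergence (a step size too large for the spring stiffnesses) is detected
    on the fix+border energy, which the border subsystem descends
    autonomously and which therefore can only rise under an unstable step;
    the *total* energy legitimately rises while an expanding target stretches
    the zero-rest-length bulk springs, so it cannot serve as the detector.

    ``bulk_on_border=True`` lets border points feel the bulk forces as well,
    making the sweep full gradient descent on the total energy (then used as
    the divergence watch).  In that mode the bulk weight trades off against
    the fixation springs, so raising ``w_bulk`` contracts the texture and
    shrinks bright-region distortion; in the default mode the interior
    equilibrium is the weighted-harmonic map of the border and is invariant
    to the overall ``w_bulk`` scale.
    """
    if max_iters < 1 or step_cap <= 0 or tol < 0:
        raise ValueError("invalid relaxation parameters")
    pos = system.positions.copy()
    w = system.weights
    fb0, bulk0 = system.energy_parts()
    watch0 = fb0 + bulk0 if bulk_on_border else fb0
    pos, energies, energies_fb, status = _relax_kernel(
        pos, system.n_border, system.fix_slot, system.fix_targets,
        system.border_indptr, system.border_indices,
        system.bulk_indptr, system.bulk_indices, system.bulk_k,
        w.w_fix, w.w_border, w.w_bulk, bulk_on_border,
        eta, step_cap, tol, max_iters, rng_seed, watch0,
    )
    system.energy_trace = energies
    system.energy_trace_fb = energies_fb
    if status == 1:
        raise RuntimeError("step too large: energy increased for 10 consecutive sweeps")
    fixed = np.nonzero(system.fix_slot >= 0)[0]
    targets = system.fix_targets[system.fix_slot[fixed]]
    dist = np.linalg.norm(pos[fixed] - targets, axis=1)
    if np.any(dist > snap_distance):
        warnings.warn(
            f"{int((dist > snap_distance).sum())} fixation point(s) further than "
            f"{snap_distance} px from target after relaxation", stacklevel=2,
        )
    pos[fixed[dist <= snap_distance]] = targets[dist <= snap_distance]
    system.positions = pos
    return pos, energies


def rasterize(
    system: PointSystem,
    target: Contour,
    source_id: str = "",
    max_empty_fraction: float = 0.5,
    margin: int = 2,
) -> RenderedCell:
    """Splat the relaxed points back to the pixel grid inside the target shape.

    Each point deposits its source intensity at its final position (rounded to
    the nearest pixel; coincident deposits are averaged).  In-mask pixels with
    no deposit are filled by inverse-distance weighting of the 8 nearest
    deposited samples; pixels outside the target mask are zero.
    """
    pts = target.points
    x0 = int(np.floor(pts[:, 0].min())) - margin
    y0 = int(np.floor(pts[:, 1].min())) - margin
    w = int(np.ceil(pts[:, 0].max())) - x0 + margin + 1
    h = int(np.ceil(pts[:, 1].max())) - y0 + margin + 1
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(pts[:, 1] - y0, pts[:, 0] - x0, shape=(h, w))
    mask[rr, cc] = True

    px = np.rint(system.positions[:, 0] - x0).astype(int)
    py = np.rint(system.positions[:, 1] - y0).astype(int)
    inside = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    np.add.at(acc, (py[inside], px[inside]), system.intensities[inside])
    np.add.at(cnt, (py[inside], px[inside]), 1.0)
    deposited = cnt > 0

    empty = mask & ~deposited
    # A warp to a larger shape cannot fill more pixels than it has points, so
    # judge emptiness against the achievable coverage, not the mask size.
    achievable = min(1.0, system.n_points / max(int(mask.sum()), 1))
    filled = int((mask & deposited).sum())
    if mask.sum() and filled < (1.0 - max_empty_fraction) * achievable * mask.sum():
        raise RuntimeError("warp collapsed: too many empty pixels before interpolation")

    out = np.zeros((h, w))
    out[deposited] = acc[deposited] / cnt[deposited]
    if empty.any() and deposited.any():
        dep_yx = np.column_stack(np.nonzero(deposited))
        tree = cKDTree(dep_yx)
        q = np.column_stack(np.nonzero(empty))
        k = min(8, len(dep_yx))
        dist, idx = tree.query(q, k=k)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        vals = out[dep_yx[idx, 0], dep_yx[idx, 1]]
        wts = 1.0 / np.maximum(dist, 1e-9)
        out[empty] = np.sum(vals * wts, axis=1) / np.sum(wts, axis=1)
    out[~mask] = 0.0
    return RenderedCell(intensity=out, mask=mask, offset=(x0, y0), source_id=source_id)


def select_patch(patches, target_area: float, rng: np.random.Generator) -> TexturePatch:
    """Uniformly pick a patch whose area is within +/-50% of the target area;
    fall back to the closest-area patch when none qualifies."""
    areas = np.array([p.area for p in patches], dtype=float)
    ok = np.abs(areas - target_area) <= 0.5 * target_area
    if ok.any():
        return patches[int(rng.choice(np.nonzero(ok)[0]))]
    return patches[int(np.argmin(np.abs(areas - target_area)))]


def warp_texture(
    patch: TexturePatch,
    target: Contour,
    weights: WarpWeights | None = None,
    fixation_stride: int = 4,
    rng_seed: int = 0,
    **relax_kwargs,
) -> RenderedCell:
    """Convenience pipeline: init_point_system -> relax -> rasterize."""
    system = init_point_system(patch, target, weights, fixation_stride)
    relax(system, rng_seed=rng_seed, **relax_kwargs)
    return rasterize(system, target, source_id=patch.source_id)
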