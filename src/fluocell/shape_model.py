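"""Statistical (PCA/ASM) shape model for cell contours.

A cell outline is represented as a closed polygon of ``N`` points sampled at
equal arc-length intervals along the boundary of a binary mask.  Training
contours are translated to their centroid, rotated onto their principal axes
and brought into point-to-point correspondence; a principal component
analysis of the aligned coordinate vectors then yields a mean shape ``x_m``
and an orthonormal mode matrix ``P``.  New shapes are drawn as

    x = x_m + P b

with mode coefficients ``b`` sampled from zero-mean Gaussians whose variances
are the PCA eigenvalues (truncated at three standard deviations, the usual
active-shape-model convention).  A minimum-size constraint rejects degenerate
small shapes: a candidate is discarded when the mean distance of its contour
points from their centroid falls below ``r_min``.

Coordinates are continuous ``(x, y)`` with pixel centers at integer positions,
origin at the top-left corner and y pointing down.  Contours are oriented
counter-clockwise (positive shoelace area in this frame) and start at the
boundary point with the largest x (ties broken by largest y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "Contour",
    "ShapeModel",
    "ShapeSample",
    "sample_contour",
    "normalize_and_correspond",
    "fit_shape_model",
    "generate_shape",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Contour:
    """Closed polygon of ``N`` equally spaced boundary points, shape (N, 2)."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError("contour needs at least 4 (x, y) points")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def mean_radius(self) -> float:
        """Mean distance of the contour points from their centroid (px)."""
        return float(np.linalg.norm(self.points - self.centroid(), axis=1).mean())

    def is_simple(self) -> bool:
        return bool(Polygon(self.points).is_simple)

    def as_vector(self) -> np.ndarray:
        """Interleaved (x1, y1, ..., xN, yN) vector of length 2N."""
        return self.points.reshape(-1)

    @staticmethod
    def from_vector(vec: np.ndarray) -> "Contour":
        return Contour(np.asarray(vec, dtype=float).reshape(-1, 2))


@dataclass
class ShapeModel:
    """PCA shape model: mean shape, orthonormal modes and eigenvalues."""

    mean_shape: np.ndarray       # length 2N
    modes: np.ndarray            # 2N x n, orthonormal columns
    eigenvalues: np.ndarray      # length n, non-negative, non-increasing
    r_min: float                 # minimum mean radius of a generated shape (px)
    n_points: int
    constraint: str = "mean_radius"   # or "coefficient"
    min_area: float = 0.0

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).reshape(-1)
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1)
        if self.mean_shape.size != 2 * self.n_points:
            raise ValueError("mean_shape length must be 2 * n_points")
        if self.modes.shape != (self.mean_shape.size, self.eigenvalues.size):
            raise ValueError("modes must be (2N, n_modes)")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        g = self.modes.T @ self.modes
        if not np.allclose(g, np.eye(self.n_modes), atol=1e-8):
            raise ValueError("mode columns must be orthonormal")
        if self.constraint not in ("mean_radius", "coefficient"):
            raise ValueError(f"unknown constraint mode {self.constraint!r}")

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)

    def mean_contour(self) -> Contour:
        return Contour.from_vector(self.mean_shape)


@dataclass(frozen=True)
class ShapeSample:
    """A generated shape: mode coefficients ``b`` and the realized contour."""

    coefficients: np.ndarray
    contour: Contour


def sample_contour(mask: np.ndarray, n_points: int) -> Contour:
    """Sample the outer boundary of a single-component binary mask.

    The boundary is extracted at sub-pixel precision (0.5 iso-level) and
    resampled to ``n_points`` arc-length-equidistant points, ordered
    counter-clockwise, starting at the boundary point with the largest x
    (ties: largest y).
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    mask = np.asarray(mask).astype(bool)
    labels, n_comp = measure.label(mask, return_num=True, connectivity=2)
    if n_comp != 1 or mask.sum() < 4:
        raise ValueError("invalid patch: mask must have exactly one component of area >= 4")
    padded = np.pad(mask, 1).astype(float)
    rings = measure.find_contours(padded, 0.5)
    ring = max(rings, key=lambda r: r.shape[0])          # outer boundary
    poly = ring[:-1, ::-1] - 1.0                          # (row, col) -> (x, y), unpad
    return _resample_polygon(poly, n_points)


def _resample_polygon(poly: np.ndarray, n_points: int) -> Contour:
    """Resample a closed polygon to equally spaced points with the package's
    orientation and start-point conventions."""
    poly = np.asarray(poly, dtype=float)
    # enforce counter-clockwise orientation (positive shoelace area)
    x, y = poly[:, 0], poly[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        poly = poly[::-1]
    # rotate the vertex list to start at max x (ties: max y)
    start = np.lexsort((poly[:, 1], poly[:, 0]))[-1]
    poly = np.roll(poly, -start, axis=0)
    seg = np.vstack([poly, poly[:1]])
    d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    perimeter = cum[-1]
    if perimeter <= 0:
        raise ValueError("degenerate polygon")
    s = np.arange(n_points) * perimeter / n_points
    xi = np.interp(s, cum, seg[:, 0])
    yi = np.interp(s, cum, seg[:, 1])
    return Contour(np.column_stack([xi, yi]))


def _principal_axis_align(points: np.ndarray) -> np.ndarray:
    """Center a contour and rotate its principal axes onto the coordinate axes."""
    pts = points - points.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate contour: points are collinear")
    # largest eigenvector -> x axis; keep a proper rotation (det = +1)
    r = evecs[:, ::-1].T
    if np.linalg.det(r) < 0:
        r[1] *= -1.0
    return pts @ r.T


def _correspondence_candidates(pts: np.ndarray) -> np.ndarray:
    """All re-indexings of a centered contour compatible with a closed polygon:
    every cyclic shift, both traversal directions, and a 180-degree rotation
    (the principal-axis ambiguity).  Shape (4N, N, 2)."""
    n = len(pts)
    shifts = np.stack([np.roll(pts, -k, axis=0) for k in range(n)])
    rev = shifts[:, ::-1, :]
    cands = np.concatenate([shifts, rev], axis=0)
    return np.concatenate([cands, -cands], axis=0)


def _best_match(pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    cands = _correspondence_candidates(pts)
    ssd = np.sum((cands - ref[None]) ** 2, axis=(1, 2))
    return cands[int(np.argmin(ssd))]


def _optimal_rotation(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares proper rotation (Kabsch) taking src onto ref."""
    h = src.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return (u @ np.diag([1.0, d]) @ vt).T


def normalize_and_correspond(contours: Sequence[Contour]) -> list[np.ndarray]:
    """Translate, rotate and re-index contours into point correspondence.

    Each contour is centered, aligned to its principal axes and cyclically
    re-indexed (allowing index reversal and the 180-degree axis ambiguity) so
    its summed squared distance to the running reference is minimal.  A second
    pass re-aligns every contour to the mean with an exhaustive correspondence
    search plus a closed-form (Kabsch) rotation.  Scale is preserved.
    Returns interleaved (x1, y1, ..., xN, yN) vectors.
    """
    if len(contours) < 2:
        raise ValueError("need at least 2 contours")
    n = contours[0].n_points
    if any(c.n_points != n for c in contours):
        raise ValueError("all contours must have the same number of points")

    aligned = [_principal_axis_align(c.points) for c in contours]
    # pass 1: match to the first contour, updating a running reference
    out = [aligned[0]]
    ref = aligned[0].copy()
    for i, pts in enumerate(aligned[1:], start=2):
        best = _best_match(pts, ref)
        out.append(best)
        ref = ref + (best - ref) / i       # running mean
    # pass 2: Procrustes-style re-alignment to the mean
    mean = np.mean(out, axis=0)
    final = []
    for pts in out:
        best = _best_match(pts, mean)
        rot = _optimal_rotation(best, mean)
        final.append(best @ rot.T)
    return [p.reshape(-1) for p in final]


def fit_shape_model(
    aligned_vectors: Sequence[np.ndarray],
    n_modes: int,
    r_min: float = 0.0,
    constraint: str = "mean_radius",
    min_area: float = 0.0,
) -> ShapeModel:
    """PCA of aligned contour vectors -> mean shape, modes and eigenvalues."""
    x = np.asarray(aligned_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 aligned vectors")
    if not (1 <= n_modes <= x.shape[0] - 1):
        raise ValueError("n_modes must be in [1, n_samples - 1]")
    mean = x.mean(axis=0)
    centered = x - mean
    # SVD of the centered data matrix gives the eigenpairs of the sample covariance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (x.shape[0] - 1)
    modes = vt[:n_modes].T
    return ShapeModel(
        mean_shape=mean,
        modes=modes,
        eigenvalues=np.maximum(eigenvalues[:n_modes], 0.0),
        r_min=float(r_min),
        n_points=x.shape[1] // 2,
        constraint=constraint,
        min_area=float(min_area),
    )


def n_modes_for_variance(aligned_vectors: Sequence[np.ndarray], frac: float = 0.98) -> int:
    """Smallest number of modes explaining ``frac`` of the total variance."""
    x = np.asarray(aligned_vectors, dtype=float)
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    ev = s**2
    cum = np.cumsum(ev) / ev.sum()
    k = int(np.searchsorted(cum, frac) + 1)
    return min(k, x.shape[0] - 1)


def _shape_is_valid(model: ShapeModel, b: np.ndarray, contour: Contour) -> bool:
    if model.constraint == "coefficient":
        # literal coefficient-space test with the pseudo-inverse of the modes
        ref = np.linalg.pinv(model.modes) @ model.mean_shape
        if np.linalg.norm(b - ref) <= model.r_min:
            return False
    else:
        if contour.mean_radius() < model.r_min:
            return False
    if model.min_area > 0 and contour.area() <= model.min_area:
        return False
    return contour.is_simple()


def generate_shape(
    model: ShapeModel,
    rng: np.random.Generator | int | None = None,
    coefficients: np.ndarray | None = None,
    max_rejections: int = 1000,
) -> ShapeSample:
    """Draw a new shape x = x_m + P b.

    Coefficients are drawn independently per mode from N(0, eigenvalue),
    truncated at +/- 3 sqrt(eigenvalue); candidates failing the minimum-size
    constraint (or self-intersecting) are rejected and redrawn.  Passing
    ``coefficients`` bypasses sampling (the constraint is still enforced).
    """
    rng = np.random.default_rng(rng)
    sigma = np.sqrt(model.eigenvalues)
    for _ in range(max_rejections):
        if coefficients is not None:
            b = np.asarray(coefficients, dtype=float).reshape(-1)
            if b.size != model.n_modes:
                raise ValueError("coefficient vector has wrong length")
        else:
            b = np.clip(rng.normal(0.0, sigma), -3.0 * sigma, 3.0 * sigma)
        contour = Contour.from_vector(model.mean_shape + model.modes @ b)
        if _shape_is_valid(model, b, contour):
            return ShapeSample(coefficients=b, contour=contour)
        if coefficients is not None:
            raise ValueError("supplied coefficients violate the size constraint")
    raise RuntimeError(
        f"model/r_min incompatible: {max_rejections} consecutive rejections"
    )


def save_model(model: ShapeModel, path) -> None:
    doc = {
        "format_version": _FORMAT_VERSION,
        "mean_shape": model.mean_shape.tolist(),
        "modes": model.modes.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "r_min": model.r_min,
        "n_points": model.n_points,
        "n_modes": model.n_modes,
        "constraint": model.constraint,
        "min_area": model.min_area,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ShapeModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unknown model format version in {path}")
    return ShapeModel(
        mean_shape=np.array(doc["mean_shape"]),
        modes=np.array(doc["modes"]),
        eigenvalues=np.array(doc["eigenvalues"]),
        r_min=doc["r_min"],
        n_points=doc["n_points"],
        constraint=doc.get("constraint", "mean_radius"),
        min_area=doc.get("min_area", 0.0),
    )
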