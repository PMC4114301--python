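"""Potential mapping 1D->3D and concentration back-mapping 3D->1D.

The forward direction assigns each 3D surface vertex the membrane potential
of its nearest compartment node (exact nearest-neighbor search under any
Minkowski metric; a k-d tree for speed, with the O(n^2) pairwise search kept
as the reference strategy).  Optional linear/bilinear interpolation over k
pseudo nearest neighbors refines the assignment when the compartment
discretization is coarse relative to the surface grid.

The reverse direction computes, per compartment, the area-weighted mean of
the concentration field over the compartment's membrane patch, multiplied by
the ratio of the ideal cylinder lateral area pi*d*l to the actual mesh patch
area — the correction for the two surfaces not being identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-12


@dataclass
class MappingIndex:
    """Spatial index over compartment-node source points.

    ``p`` is the Minkowski exponent of the distance (2 = Euclidean).
    Tie-breaking contract: at exactly equal distances the lowest source
    index wins, for both the tree and the pairwise search.
    """

    points: np.ndarray
    p: float = 2.0

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or len(self.points) == 0:
            raise ConfigError("need a non-empty (n, d) source point array")
        self.tree = cKDTree(self.points)

    @property
    def n(self) -> int:
        return len(self.points)


def build_index(points, p: float = 2.0) -> MappingIndex:
    """Build a k-d tree index over the source points (O(n log n))."""
    return MappingIndex(np.asarray(points, float), p)


def minkowski_distance(p_vec, q_vec, p: float = 2.0) -> np.ndarray:
    d = np.abs(np.asarray(p_vec, float) - np.asarray(q_vec, float))
    if np.isinf(p):
        return d.max(axis=-1)
    return (d ** p).sum(axis=-1) ** (1.0 / p)


def _tie_broken(indices: np.ndarray, distances: np.ndarray):
    """Among candidates sorted by distance, pick the lowest index among
    those tied (to relative tolerance) with the best distance."""
    best = distances[..., 0]
    tol = np.maximum(best * _TIE_RTOL, 1e-300)
    tied = distances <= (best[..., None] + tol[..., None])
    masked = np.where(tied, indices, np.iinfo(np.int64).max)
    winner = masked.min(axis=-1)
    d = np.take_along_axis(
        distances, np.argmax(indices == winner[..., None], axis=-1)[..., None],
        axis=-1)[..., 0]
    return winner, d


def nearest(index: MappingIndex, q) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest source point(s) for query point(s) ``q``.

    Returns (source index, distance); vectorized over a (m, d) query array.
    """
    q = np.atleast_2d(np.asarray(q, float))
    k = min(index.n, 8)
    dist, idx = index.tree.query(q, k=k, p=index.p)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    win, d = _tie_broken(idx, dist)
    if q.shape[0] == 1:
        return int(win[0]), float(d[0])
    return win, d


def nearest_bruteforce(index: MappingIndex, q) -> tuple[np.ndarray, np.ndarray]:
    """O(n*m) pairwise-comparison nearest neighbor (reference strategy)."""
    q = np.atleast_2d(np.asarray(q, float))
    out_i = np.empty(len(q), np.int64)
    out_d = np.empty(len(q))
    chunk = max(1, int(2e7) // max(index.n, 1))
    for s in range(0, len(q), chunk):
        block = q[s:s + chunk]
        d = minkowski_distance(block[:, None, :], index.points[None, :, :],
                               index.p)
        best = d.min(axis=1)
        tol = np.maximum(best * _TIE_RTOL, 1e-300)
        tied = d <= best[:, None] + tol[:, None]
        idx = np.argmax(tied, axis=1)   # first (lowest) tied index
        out_i[s:s + chunk] = idx
        out_d[s:s + chunk] = d[np.arange(len(block)), idx]
    if len(q) == 1:
        return int(out_i[0]), float(out_d[0])
    return out_i, out_d


@dataclass
class PotentialFrame:
    """Membrane potentials at the compartment nodes at one instant."""

    t: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


def map_potentials(index: MappingIndex, frame: PotentialFrame, targets,
                   mode: str = "nearest", k: int = 4,
                   cutoff: float | None = None) -> np.ndarray:
    """Assign a membrane potential to every target (surface) vertex.

    nearest   : copy the nearest source's value.
    linear    : among the k nearest sources, project the target onto every
                segment through a source pair; whenever the projection is
                closer than the current best distance, interpolate linearly
                along that segment.
    bilinear  : same with planes through coplanar 4-subsets and bilinear
                interpolation at the in-plane projection.
    Both interpolating modes fall back to the nearest value when the nearest
    distance exceeds ``cutoff``.
    """
    if len(frame.values) != index.n:
        raise ConfigError("frame values and index sources differ in length")
    targets = np.atleast_2d(np.asarray(targets, float))
    nn_idx, nn_dist = nearest(index, targets)
    nn_idx = np.atleast_1d(nn_idx)
    nn_dist = np.atleast_1d(nn_dist)
    out = frame.values[nn_idx].astype(float)
    if mode == "nearest":
        return out
    if mode not in ("linear", "bilinear"):
        raise ConfigError(f"unknown mapping mode '{mode}'")
    kmin = 2 if mode == "linear" else 4
    if k < kmin:
        raise ConfigError(f"mode '{mode}' needs k >= {kmin}")
    if k > index.n:
        raise ConfigError(f"k={k} exceeds the {index.n} source points")
    if cutoff is None:
        cutoff = np.inf
    kd, ki = index.tree.query(targets, k=k, p=index.p)
    if k == 1:
        kd, ki = kd[:, None], ki[:, None]
    for m in range(len(targets)):
        if nn_dist[m] > cutoff:
            continue
        pts = index.points[ki[m]]
        vals = frame.values[ki[m]]
        if mode == "linear":
            out[m] = _interp_linear(targets[m], pts, vals, nn_dist[m], out[m])
        else:
            out[m] = _interp_bilinear(targets[m], pts, vals, nn_dist[m],
                                      out[m])
    return out


def _interp_linear(q, pts, vals, best_dist, best_val):
    for i, j in combinations(range(len(pts)), 2):
        a, b = pts[i], pts[j]
        ab = b - a
        denom = ab @ ab
        if denom == 0:
            continue
        t = np.clip((q - a) @ ab / denom, 0.0, 1.0)
        proj = a + t * ab
        d = np.linalg.norm(q - proj)
        if d <= best_dist:
            best_dist = d
            best_val = (1 - t) * vals[i] + t * vals[j]
    return best_val


def _interp_bilinear(q, pts, vals, best_dist, best_val, coplanar_tol=1e-6):
    for subset in combinations(range(len(pts)), 4):
        p4 = pts[list(subset)]
        v4 = vals[list(subset)]
        e1, e2 = p4[1] - p4[0], p4[2] - p4[0]
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n)
        scale = max(np.linalg.norm(e1), np.linalg.norm(e2), 1e-300)
        if nn < 1e-12 * scale ** 2:
            continue  # first three collinear
        n = n / nn
        # determinant test: 4th point must be coplanar with the first three
        if abs((p4[3] - p4[0]) @ n) > coplanar_tol * scale:
            continue
        proj = q - ((q - p4[0]) @ n) * n
        d = np.linalg.norm(q - proj)
        if d > best_dist:
            continue
        val = _bilinear_on_quad(proj, p4, v4, n)
        if val is not None:
            best_dist = d
            best_val = val
    return best_val


def _bilinear_on_quad(proj, p4, v4, n):
    """Inverse-bilinear interpolation on the angularly ordered quad.

    Returns None for degenerate/non-convex orderings.  The (s, t)
    coordinates are clamped to the unit square so the result is a convex
    combination of the four corner values.
    """
    centroid = p4.mean(axis=0)
    # 2D frame in the plane
    u = p4[0] - centroid
    u = u - (u @ n) * n
    if np.linalg.norm(u) < 1e-14:
        return None
    u /= np.linalg.norm(u)
    w = np.cross(n, u)
    ang = np.arctan2((p4 - centroid) @ w, (p4 - centroid) @ u)
    order = np.argsort(ang)
    a, b, c, d = p4[order]
    va, vb, vc, vd = v4[order]
    # Newton for bilinear coordinates: X(s,t) = (1-s)(1-t)a + s(1-t)b
    #                                          + s t c + (1-s) t d
    s = t = 0.5
    for _ in range(25):
        x = ((1 - s) * (1 - t) * a + s * (1 - t) * b + s * t * c
             + (1 - s) * t * d)
        r = x - proj
        if np.linalg.norm(r) < 1e-12:
            break
        dxds = (1 - t) * (b - a) + t * (c - d)
        dxdt = (1 - s) * (d - a) + s * (c - b)
        J = np.column_stack([dxds, dxdt])
        sol, *_ = np.linalg.lstsq(J, -r, rcond=None)
        s += sol[0]
        t += sol[1]
        s, t = float(np.clip(s, -0.5, 1.5)), float(np.clip(t, -0.5, 1.5))
    s, t = float(np.clip(s, 0, 1)), float(np.clip(t, 0, 1))
    return ((1 - s) * (1 - t) * va + s * (1 - t) * vb + s * t * vc
            + (1 - s) * t * vd)


def map_concentration_back(boundary_values: np.ndarray,
                           patch_of_triangle: np.ndarray,
                           triangle_areas: np.ndarray,
                           triangles: np.ndarray,
                           cylinder_areas: np.ndarray,
                           parent_indices: np.ndarray | None = None
                           ) -> np.ndarray:
    """Per-compartment concentration from a field on the membrane vertices.

    Parameters
    ----------
    boundary_values : field values at surface vertices (uM)
    patch_of_triangle : compartment index per surface triangle (-1 = skip)
    triangle_areas, triangles : surface geometry (vertex indices local to
        ``boundary_values``)
    cylinder_areas : ideal 1D lateral areas pi*d*l per compartment (um^2)
    parent_indices : per-compartment parent (empty patches inherit the
        parent's value)

    Returns per-compartment [Ca] = (pi*d*l / ||patch||) * mean_patch(u),
    with the area-weighted mean taken by distributing each triangle's area
    equally onto its three vertices.
    """
    n_comp = len(cylinder_areas)
    tri_mean = boundary_values[triangles].mean(axis=1)
    patch_area = np.zeros(n_comp)
    patch_integral = np.zeros(n_comp)
    valid = patch_of_triangle >= 0
    np.add.at(patch_area, patch_of_triangle[valid], triangle_areas[valid])
    np.add.at(patch_integral, patch_of_triangle[valid],
              (triangle_areas * tri_mean)[valid])
    out = np.empty(n_comp)
    empty = patch_area <= 0
    nz = ~empty
    mean_u = np.zeros(n_comp)
    mean_u[nz] = patch_integral[nz] / patch_area[nz]
    out[nz] = mean_u[nz] * cylinder_areas[nz] / patch_area[nz]
    if empty.any():
        if parent_indices is None:
            raise ConfigError("empty patch and no parent information")
        for i in np.nonzero(empty)[0]:
            j = i
            hops = 0
            while patch_area[j] <= 0 and parent_indices[j] >= 0 and hops < n_comp:
                j = parent_indices[j]
                hops += 1
            if patch_area[j] <= 0:
                raise ConfigError(f"compartment {i}: no ancestor has a patch")
            out[i] = mean_u[j] * cylinder_areas[j] / patch_area[j]
            logger.warning("compartment %d has an empty membrane patch; "
                           "inheriting ancestor %d", i, j)
    return out
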