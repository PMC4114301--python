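"""Surface and volume mesh generation from point-diameter morphologies.

The neuron geometry is the union of frusta (one per morphology edge, flat
capped at terminal tips) and a sphere per soma.  Meshing runs through a
single uniform construction for every topology (straight cables,
bifurcations, somata, interior obstacles):

1. the signed distance field (SDF) of the frustum/sphere union — minus any
   obstacle cylinders, carved out by CSG difference — is sampled on a
   regular lattice of spacing ``h``;
2. lattice cells inside the geometry are subdivided into five tetrahedra
   with alternating (checkerboard) parity so faces conform across cells;
3. boundary vertices are snapped onto the exact zero level set and relaxed
   tangentially, under a quality guard that blends vertices back toward
   their lattice positions wherever an element would drop below the
   aspect-ratio stability guideline (AR >= 0.1);
4. the triangular surface mesh is the oriented boundary of the tetrahedral
   mesh, so the two are conforming by construction, watertight, and an
   interior obstacle changes the cytosol mesh without touching the outer
   membrane triangulation.

Aspect ratios are normalized inradius/circumradius ratios (2 r_in/r_circ
for triangles, 3 r_in/r_circ for tetrahedra; the regular element scores 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cable1d import ObstacleSpec
from .errors import ConfigError, MeshingError
from .morphology import CompartmentModel, MorphologyGraph, edge_order

logger = logging.getLogger(__name__)

REGION_MEMBRANE = 0
REGION_CAP = 1
REGION_OBSTACLE = 2

_INSIDE_MARGIN = 0.1     # kept-cell threshold, in units of h
_GUARD_AR = 0.1          # stability guideline for tetrahedra


# ---------------------------------------------------------------------------
# signed distance field

class GeometrySDF:
    """SDF of the morphology union, minus obstacle cylinders."""

    def __init__(self, graph: MorphologyGraph,
                 obstacles: list[ObstacleSpec] | None = None):
        self.graph = graph
        self.edges = edge_order(graph)
        self.obstacles = [o for o in (obstacles or [])
                          if o.hindrance > 0.0]
        self._edge_geom = []
        pos, rad = graph.positions, graph.radii
        deg = graph.degree()
        for (pi, ci) in self.edges:
            a, b = pos[pi], pos[ci]
            L = float(np.linalg.norm(b - a))
            u = (b - a) / L if L > 0 else np.array([1.0, 0, 0])
            self._edge_geom.append((a, u, L, rad[pi], rad[ci],
                                    deg[pi] == 1, deg[ci] == 1))
        self.soma = graph.soma_center_radius()
        self._obs_geom = []
        for o in self.obstacles:
            a, u, L, ra, rb, _, _ = self._edge_geom[o.edge]
            s = np.clip(o.arc_position, 0.0, L)
            center = a + s * u
            r_local = ra + (rb - ra) * s / L
            self._obs_geom.append((center, u, o.length / 2.0,
                                   o.hindrance * r_local))

    # -- primitive distances ------------------------------------------------

    def _edge_sdf(self, x: np.ndarray, geom) -> np.ndarray:
        a, u, L, ra, rb, _, _ = geom
        rel = x - a
        ax = rel @ u
        radial = np.linalg.norm(rel - ax[:, None] * u, axis=1)
        r_at = ra + (rb - ra) * np.clip(ax / L, 0.0, 1.0)
        dx = radial - r_at
        dy = np.maximum(-ax, ax - L)
        return (np.minimum(np.maximum(dx, dy), 0.0)
                + np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0)))

    def _obstacle_sdf(self, x: np.ndarray, geom) -> np.ndarray:
        c, u, hl, r = geom
        rel = x - c
        ax = rel @ u
        radial = np.linalg.norm(rel - ax[:, None] * u, axis=1)
        dx = radial - r
        dy = np.abs(ax) - hl
        return (np.minimum(np.maximum(dx, dy), 0.0)
                + np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0)))

    # -- public -------------------------------------------------------------

    def outer(self, x: np.ndarray) -> np.ndarray:
        """Union SDF of the cell without obstacle carving."""
        x = np.atleast_2d(x)
        f = np.full(len(x), np.inf)
        for geom in self._edge_geom:
            f = np.minimum(f, self._edge_sdf(x, geom))
        if self.soma is not None:
            c, r = self.soma
            f = np.minimum(f, np.linalg.norm(x - c, axis=1) - r)
        return f

    def obstacle(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        f = np.full(len(x), np.inf)
        for geom in self._obs_geom:
            f = np.minimum(f, self._obstacle_sdf(x, geom))
        return f

    def __call__(self, x: np.ndarray) -> np.ndarray:
        f = self.outer(x)
        if self._obs_geom:
            f = np.maximum(f, -self.obstacle(x))
        return f

    def gradient(self, x: np.ndarray, eps: float) -> np.ndarray:
        g = np.empty_like(x)
        for d in range(3):
            step = np.zeros(3)
            step[d] = eps
            g[:, d] = (self(x + step) - self(x - step)) / (2 * eps)
        norm = np.linalg.norm(g, axis=1)
        norm[norm < 1e-12] = 1.0
        return g / norm[:, None]

    def project(self, x: np.ndarray, h: float, iters: int = 4) -> np.ndarray:
        """Newton projection of points onto the zero level set, with the
        total displacement clamped to 0.95 h."""
        x0 = x.copy()
        y = x.copy()
        for _ in range(iters):
            f = self(y)
            g = self.gradient(y, 0.01 * h)
            y = y - f[:, None] * g
        disp = y - x0
        d = np.linalg.norm(disp, axis=1)
        over = d > 0.95 * h
        if over.any():
            disp[over] *= (0.95 * h / d[over])[:, None]
        return x0 + disp

    def classify_faces(self, centroids: np.ndarray) -> np.ndarray:
        """Region code per boundary face centroid."""
        n = len(centroids)
        region = np.full(n, REGION_MEMBRANE, int)
        f_out = np.abs(self.outer(centroids))
        if self._obs_geom:
            f_obs = np.abs(self.obstacle(centroids))
            region[f_obs < f_out] = REGION_OBSTACLE
        outer_mask = region == REGION_MEMBRANE
        if outer_mask.any():
            caps = self._cap_mask(centroids[outer_mask])
            idx = np.nonzero(outer_mask)[0]
            region[idx[caps]] = REGION_CAP
        return region

    def nearest_edge_arc(self, x: np.ndarray):
        """Winning edge index and clamped arc position per point (soma -> -1)."""
        x = np.atleast_2d(x)
        n = len(x)
        best = np.full(n, np.inf)
        edge_idx = np.full(n, -1, int)
        arc = np.zeros(n)
        for e, geom in enumerate(self._edge_geom):
            a, u, L, *_ = geom
            f = self._edge_sdf(x, geom)
            better = f < best
            best[better] = f[better]
            edge_idx[better] = e
            s = np.clip((x - a) @ u, 0.0, L)
            arc[better] = s[better]
        if self.soma is not None:
            c, r = self.soma
            f = np.linalg.norm(x - c, axis=1) - r
            better = f < best
            edge_idx[better] = -1
        return edge_idx, arc

    def _cap_mask(self, x: np.ndarray) -> np.ndarray:
        """True where the nearest feature is a flat terminal cap."""
        n = len(x)
        best = np.full(n, np.inf)
        is_cap = np.zeros(n, bool)
        for geom in self._edge_geom:
            a, u, L, ra, rb, term_a, term_b = geom
            rel = x - a
            ax = rel @ u
            radial = np.linalg.norm(rel - ax[:, None] * u, axis=1)
            r_at = ra + (rb - ra) * np.clip(ax / L, 0.0, 1.0)
            dx = radial - r_at
            dy = np.maximum(-ax, ax - L)
            f = (np.minimum(np.maximum(dx, dy), 0.0)
                 + np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0)))
            better = f < best
            best[better] = f[better]
            cap_here = (dy > dx) & np.where(ax < L / 2.0, term_a, term_b)
            is_cap[better] = cap_here[better]
        if self.soma is not None:
            c, r = self.soma
            f = np.linalg.norm(x - c, axis=1) - r
            is_cap[f < best] = False
        return is_cap


# ---------------------------------------------------------------------------
# mesh containers

@dataclass
class SurfaceMesh:
    """Triangulated boundary: vertices [um], outward-oriented triangles,
    per-triangle region (membrane/cap/obstacle) and compartment patch."""

    vertices: np.ndarray
    triangles: np.ndarray
    region: np.ndarray
    patch_label: np.ndarray | None = None
    vertex_map: np.ndarray | None = None     # into the paired volume mesh
    provenance: dict = field(default_factory=dict)
    _paired_volume: "VolumeMesh | None" = None

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def area(self, region: int | None = None) -> float:
        a = self.triangle_areas()
        if region is None:
            return float(a.sum())
        return float(a[self.region == region].sum())

    def edge_counts(self):
        e = np.concatenate([self.triangles[:, [0, 1]],
                            self.triangles[:, [1, 2]],
                            self.triangles[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two triangles."""
        return bool(np.all(self.edge_counts() == 2))

    def euler_characteristic(self) -> int:
        used = np.unique(self.triangles)
        e = np.concatenate([self.triangles[:, [0, 1]],
                            self.triangles[:, [1, 2]],
                            self.triangles[:, [2, 0]]])
        e.sort(axis=1)
        n_edges = len(np.unique(e, axis=0))
        return len(used) - n_edges + len(self.triangles)

    def n_components(self) -> int:
        import scipy.sparse as sp
        n = len(self.vertices)
        t = self.triangles
        rows = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
        cols = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
        g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        ncomp, labels = sp.csgraph.connected_components(g, directed=False)
        return len(np.unique(labels[np.unique(t)]))


@dataclass
class VolumeMesh:
    """Conforming tetrahedral mesh of the cytosol."""

    vertices: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray       # global vertex indices, outward
    boundary_region: np.ndarray
    provenance: dict = field(default_factory=dict)

    def tet_volumes(self) -> np.ndarray:
        p = self.vertices[self.tets]
        return np.einsum("ij,ij->i",
                         np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                         p[:, 3] - p[:, 0]) / 6.0

    def volume(self) -> float:
        return float(self.tet_volumes().sum())

    def boundary_vertices(self, region: int | None = None) -> np.ndarray:
        faces = self.boundary_faces
        if region is not None:
            faces = faces[self.boundary_region == region]
        return np.unique(faces)

    def boundary_face_areas(self) -> np.ndarray:
        p = self.vertices[self.boundary_faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def boundary_vertex_areas(self, region: int | None = None) -> np.ndarray:
        """Lumped boundary measure: one third of each incident face area,
        indexed over all mesh vertices (zero off the chosen boundary)."""
        w = np.zeros(len(self.vertices))
        faces = self.boundary_faces
        areas = self.boundary_face_areas()
        if region is not None:
            keep = self.boundary_region == region
            faces, areas = faces[keep], areas[keep]
        for c in range(3):
            np.add.at(w, faces[:, c], areas / 3.0)
        return w


# ---------------------------------------------------------------------------
# lattice construction

_EVEN_TETS = np.array([
    [0b000, 0b100, 0b010, 0b001],
    [0b110, 0b010, 0b100, 0b111],
    [0b101, 0b100, 0b001, 0b111],
    [0b011, 0b001, 0b010, 0b111],
    [0b100, 0b010, 0b001, 0b111],
])
# odd parity: mirror in x (bit 2) keeps shared-face diagonals conforming;
# the mirror flips orientation, so two vertices are swapped back
_ODD_TETS = (_EVEN_TETS ^ 0b100)[:, [1, 0, 2, 3]]


def _voxel_pinch_fix(kept: np.ndarray, f: np.ndarray, max_iter: int = 10):
    """Remove edge/corner-adjacent voxel pairs that would pinch the
    boundary surface, by filling the face-neighbor with the smaller SDF."""
    for _ in range(max_iter):
        changed = False
        for ax1, ax2 in ((0, 1), (0, 2), (1, 2)):
            for d1, d2 in ((1, 1), (1, -1)):
                sl = _shift2(kept, ax1, d1, ax2, d2)
                a, b, n1, n2 = sl
                pinch = kept[a] & kept[b] & ~kept[n1] & ~kept[n2]
                if pinch.any():
                    changed = True
                    pick1 = f[n1] <= f[n2]
                    fill1 = pinch & pick1
                    fill2 = pinch & ~pick1
                    kept[n1] |= fill1
                    kept[n2] |= fill2
        if not changed:
            break
    return kept


def _shift2(kept, ax1, d1, ax2, d2):
    """Index tuples (cell, diagonal cell, neighbor1, neighbor2) for the
    pinch test along the (ax1, ax2) plane diagonal (d1, d2)."""
    def sl(shift_spec):
        out = [slice(None)] * 3
        for ax, s in shift_spec:
            out[ax] = slice(1, None) if s == 1 else slice(None, -1)
        return tuple(out)

    def pos(ax, d):
        return (ax, 1) if d == 1 else (ax, 0)

    # cell at low corner of the diagonal
    a = sl([(ax1, 0 if d1 == 1 else 1), (ax2, 0 if d2 == 1 else 1)])
    b = sl([(ax1, 1 if d1 == 1 else 0), (ax2, 1 if d2 == 1 else 0)])
    n1 = sl([(ax1, 1 if d1 == 1 else 0), (ax2, 0 if d2 == 1 else 1)])
    n2 = sl([(ax1, 0 if d1 == 1 else 1), (ax2, 1 if d2 == 1 else 0)])
    return a, b, n1, n2


def build_mesh_pair(graph: MorphologyGraph, h: float,
                    obstacles: list[ObstacleSpec] | None = None
                    ) -> tuple[SurfaceMesh, VolumeMesh]:
    """Generate the conforming (surface, volume) mesh pair at lattice
    spacing ``h`` [um]."""
    if h <= 0:
        raise ConfigError("lattice spacing h must be positive")
    sdf = GeometrySDF(graph, obstacles)
    pos, rad = graph.positions, graph.radii
    pad = rad.max() + 2 * h
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    lo = np.floor(lo / h) * h
    dims = np.ceil((hi - lo) / h).astype(int) + 1
    nx, ny, nz = dims
    if nx * ny * nz > 4.0e6:
        raise MeshingError(
            f"lattice {dims} too large at h={h}; coarsen the resolution")

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    centers = (np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) + 0.5) \
        * h + lo
    f = sdf(centers).reshape(nx, ny, nz)
    kept = f <= -_INSIDE_MARGIN * h
    if not kept.any():
        raise MeshingError("no interior lattice cells; h too coarse for "
                           "this geometry")
    # drop debris components (face connectivity); keep any component with
    # at least 8 cells so a sealed obstacle still leaves both sides meshed
    labels, ncomp = ndimage.label(kept)
    if ncomp > 1:
        sizes = ndimage.sum_labels(kept, labels, index=np.arange(1, ncomp + 1))
        for lab, size in enumerate(sizes, start=1):
            if size < 8:
                kept[labels == lab] = False
    kept = _voxel_pinch_fix(kept, f)

    surface, volume = _tets_from_voxels(kept, lo, h, sdf)
    prov = {"graph": graph, "h": h, "obstacles": list(obstacles or [])}
    surface.provenance.update(prov)
    volume.provenance.update(prov)
    surface._paired_volume = volume
    return surface, volume


def _tets_from_voxels(kept, lo, h, sdf):
    nx, ny, nz = kept.shape
    vi, vj, vk = np.nonzero(kept)
    n_vox = len(vi)

    def node_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    corners = np.empty((n_vox, 8), np.int64)
    for bit in range(8):
        dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
        corners[:, bit] = node_id(vi + dx, vj + dy, vk + dz)

    parity = (vi + vj + vk) % 2
    tets_global = np.empty((n_vox, 5, 4), np.int64)
    for g, table in ((0, _EVEN_TETS), (1, _ODD_TETS)):
        mask = parity == g
        tets_global[mask] = corners[mask][:, table]
    tets_global = tets_global.reshape(-1, 4)

    used, tets = np.unique(tets_global, return_inverse=True)
    tets = tets.reshape(-1, 4)
    gi = used // ((ny + 1) * (nz + 1))
    gj = (used // (nz + 1)) % (ny + 1)
    gk = used % (nz + 1)
    verts = np.column_stack([gi, gj, gk]) * h + lo
    lattice_verts = verts.copy()

    # boundary faces (appear once among all tet faces)
    faces = np.concatenate([tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
                            tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]])
    opp = np.concatenate([tets[:, 3], tets[:, 2], tets[:, 1], tets[:, 0]])
    key = np.sort(faces, axis=1)
    uniq, first, counts = np.unique(key, axis=0, return_index=True,
                                    return_counts=True)
    b_idx = first[counts == 1]
    b_faces = faces[b_idx]
    b_opp = opp[b_idx]

    boundary_vert = np.unique(b_faces)
    is_boundary = np.zeros(len(verts), bool)
    is_boundary[boundary_vert] = True

    # snap boundary vertices to the exact surface, relax, guard quality
    verts[boundary_vert] = sdf.project(verts[boundary_vert], h)
    nbr_rows, nbr_cols = _boundary_adjacency(b_faces)
    for _ in range(2):
        verts = _tangential_smooth(verts, boundary_vert, nbr_rows, nbr_cols,
                                   sdf, h)
    verts = _quality_guard(verts, lattice_verts, tets, is_boundary, h)

    vols = _signed_volumes(verts, tets)
    neg = vols <= 0
    if neg.any():
        raise MeshingError(f"{neg.sum()} inverted tetrahedra after snapping"
                           " (reduce h or report this geometry)")

    # orient boundary faces outward (normal away from the opposite vertex)
    p = verts[b_faces]
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    inward = np.einsum("ij,ij->i", nrm, verts[b_opp] - p[:, 0]) > 0
    b_faces[inward] = b_faces[inward][:, [0, 2, 1]]

    centroids = verts[b_faces].mean(axis=1)
    region = sdf.classify_faces(centroids)

    volume = VolumeMesh(vertices=verts, tets=tets, boundary_faces=b_faces,
                        boundary_region=region)
    # surface mesh re-indexed over its own vertex set
    local = -np.ones(len(verts), np.int64)
    local[boundary_vert] = np.arange(len(boundary_vert))
    surface = SurfaceMesh(vertices=verts[boundary_vert],
                          triangles=local[b_faces],
                          region=region.copy(),
                          vertex_map=boundary_vert)
    return surface, volume


def _boundary_adjacency(b_faces):
    e = np.concatenate([b_faces[:, [0, 1]], b_faces[:, [1, 2]],
                        b_faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return rows, cols


def _tangential_smooth(verts, boundary_vert, rows, cols, sdf, h,
                       weight=0.5):
    acc = np.zeros_like(verts)
    cnt = np.zeros(len(verts))
    np.add.at(acc, rows, verts[cols])
    np.add.at(cnt, rows, 1.0)
    target = verts.copy()
    nz = cnt > 0
    target[nz] = acc[nz] / cnt[nz][:, None]
    out = verts.copy()
    out[boundary_vert] = ((1 - weight) * verts[boundary_vert]
                          + weight * target[boundary_vert])
    out[boundary_vert] = sdf.project(out[boundary_vert], h, iters=2)
    return out


def _signed_volumes(verts, tets):
    p = verts[tets]
    return np.einsum("ij,ij->i",
                     np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                     p[:, 3] - p[:, 0]) / 6.0


def _tet_aspect_ratios(verts, tets):
    p = verts[tets]
    vol = np.abs(_signed_volumes(verts, tets))
    # face areas
    combos = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    area_sum = np.zeros(len(tets))
    for (a, b, c) in combos:
        area_sum += 0.5 * np.linalg.norm(
            np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1)
    r_in = np.where(area_sum > 0, 3.0 * vol / area_sum, 0.0)
    # circumradius via the circumcenter linear system
    A = 2.0 * (p[:, 1:] - p[:, :1])
    rhs = np.einsum("ijk,ijk->ij", p[:, 1:], p[:, 1:]) \
        - np.einsum("ijk,ijk->ij", p[:, :1], p[:, :1])
    det_ok = np.abs(np.linalg.det(A)) > 1e-30
    center = np.zeros((len(tets), 3))
    if det_ok.any():
        center[det_ok] = np.linalg.solve(A[det_ok],
                                         rhs[det_ok][..., None])[..., 0]
    r_circ = np.linalg.norm(center - p[:, 0], axis=1)
    ar = np.zeros(len(tets))
    good = det_ok & (r_circ > 0) & (vol > 0)
    ar[good] = 3.0 * r_in[good] / r_circ[good]
    return ar


def _tri_aspect_ratios(verts, tris):
    p = verts[tris]
    a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    b = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    area = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    s = 0.5 * (a + b + c)
    good = (area > 0) & (s > 0)
    ar = np.zeros(len(tris))
    r_in = np.zeros(len(tris))
    r_in[good] = area[good] / s[good]
    r_circ = np.ones(len(tris))
    r_circ[good] = a[good] * b[good] * c[good] / (4.0 * area[good])
    ar[good] = 2.0 * r_in[good] / r_circ[good]
    return ar


def _quality_guard(verts, lattice_verts, tets, is_boundary, h,
                   max_rounds: int = 8):
    """Blend boundary vertices of low-quality or inverted tets back toward
    their lattice positions until all tets satisfy the AR guideline."""
    out = verts.copy()
    for _ in range(max_rounds):
        vols = _signed_volumes(out, tets)
        ar = _tet_aspect_ratios(out, tets)
        bad = (vols <= 1e-9 * h ** 3) | (ar < _GUARD_AR)
        if not bad.any():
            break
        bad_verts = np.unique(tets[bad])
        bad_verts = bad_verts[is_boundary[bad_verts]]
        if len(bad_verts) == 0:
            bad_verts = np.unique(tets[bad])
        out[bad_verts] = 0.5 * out[bad_verts] + 0.5 * lattice_verts[bad_verts]
    return out


# ---------------------------------------------------------------------------
# public operations

def resolution_from_n_circle(graph: MorphologyGraph, n_circle: int) -> float:
    """Lattice spacing equivalent to ``n_circle`` vertices around the
    thinnest neurite: h = pi * r_min / n_circle."""
    if n_circle < 6:
        raise ConfigError("n_circle must be >= 6")
    return float(np.pi * graph.radii.min() / n_circle)


def surface_from_graph(graph: MorphologyGraph, n_circle: int = 16,
                       h: float | None = None,
                       obstacles: list[ObstacleSpec] | None = None
                       ) -> SurfaceMesh:
    """Watertight triangulated plasma membrane of the morphology.

    ``n_circle`` controls resolution as the approximate vertex count around
    the thinnest neurite's circumference; ``h`` overrides it directly as the
    lattice spacing [um].
    """
    if h is None:
        h = resolution_from_n_circle(graph, n_circle)
    surface, _ = build_mesh_pair(graph, h, obstacles)
    if not surface.is_watertight():
        raise MeshingError("generated surface is not watertight")
    return surface


def tetrahedralize(surface: SurfaceMesh) -> VolumeMesh:
    """Conforming tetrahedral cytosol mesh for a generated surface.

    The volume is generated together with the surface (the surface is the
    oriented boundary of the tetrahedral mesh), so boundary triangles map
    one-to-one onto surface triangles.  Foreign, non-generated surfaces are
    rejected; non-watertight input is a precondition error.
    """
    if not surface.is_watertight():
        raise MeshingError("tetrahedralize requires a watertight surface")
    if surface._paired_volume is not None:
        return surface._paired_volume
    prov = surface.provenance
    if "graph" not in prov:
        raise MeshingError("surface lacks generation provenance; meshing "
                           "arbitrary external surfaces is unsupported")
    _, volume = build_mesh_pair(prov["graph"], prov["h"],
                                prov.get("obstacles"))
    surface._paired_volume = volume
    return volume


def insert_obstacle(graph: MorphologyGraph, spec: ObstacleSpec,
                    n_circle: int = 16, h: float | None = None
                    ) -> tuple[SurfaceMesh, VolumeMesh, dict]:
    """Mesh the cytosol with a cylindrical obstacle carved out.

    Returns (surface, volume, record); the record holds the obstacle's
    nominal radius/volume and the measured cytosol volume deficit relative
    to the obstacle-free mesh.  The outer membrane triangulation is
    unaffected by the insertion (H = 0 reproduces the obstacle-free meshes
    exactly).
    """
    if h is None:
        h = resolution_from_n_circle(graph, n_circle)
    geom = GeometrySDF(graph, [spec])
    if spec.edge >= len(geom.edges):
        raise ConfigError(f"obstacle edge {spec.edge} out of range")
    a, u, L, ra, rb, _, _ = geom._edge_geom[spec.edge]
    if spec.length > L:
        raise ConfigError("obstacle longer than its host edge")
    surface0, volume0 = build_mesh_pair(graph, h)
    surface, volume = build_mesh_pair(graph, h, [spec])
    r_local = ra + (rb - ra) * np.clip(spec.arc_position / L, 0, 1)
    r_obs = spec.hindrance * r_local
    record = {
        "hindrance": spec.hindrance,
        "radius_um": float(r_obs),
        "length_um": spec.length,
        "nominal_volume_um3": float(np.pi * r_obs ** 2 * spec.length),
        "nominal_lateral_area_um2": float(2 * np.pi * r_obs * spec.length),
        "cytosol_volume_um3": volume.volume(),
        "volume_deficit_um3": volume0.volume() - volume.volume(),
    }
    return surface, volume, record


def aspect_ratio_report(mesh: SurfaceMesh | VolumeMesh, bins: int = 20
                        ) -> dict:
    """Min/max/histogram of normalized aspect ratios; degenerate elements
    are reported as AR 0 and flagged."""
    if isinstance(mesh, SurfaceMesh):
        ar = _tri_aspect_ratios(mesh.vertices, mesh.triangles)
        kind = "triangle"
    elif isinstance(mesh, VolumeMesh):
        ar = _tet_aspect_ratios(mesh.vertices, mesh.tets)
        kind = "tetrahedron"
    else:
        raise ConfigError("expected a SurfaceMesh or VolumeMesh")
    hist, edges = np.histogram(ar, bins=bins, range=(0.0, 1.0))
    return {"kind": kind, "min": float(ar.min()), "max": float(ar.max()),
            "mean": float(ar.mean()), "histogram": hist,
            "bin_edges": edges, "n_degenerate": int((ar == 0).sum()),
            "values": ar}


def assign_patches(surface: SurfaceMesh, model: CompartmentModel
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label every membrane triangle with its compartment.

    Membership is by arc-length projection of the triangle centroid onto
    the morphology polyline (not Euclidean distance to compartment centers,
    so curved neurites do not mislabel).  Cap triangles are assigned to the
    nearest compartment; obstacle-wall triangles get label -1 (they are not
    plasma membrane).  Returns (labels, patch_areas, cylinder_areas) and
    stores the labels on ``surface.patch_label``.
    """
    sdf = GeometrySDF(model.graph,
                      surface.provenance.get("obstacles") or None)
    centroids = surface.vertices[surface.triangles].mean(axis=1)
    edge_idx, arc = sdf.nearest_edge_arc(centroids)
    labels = np.full(len(surface.triangles), -1, np.int64)

    # per-edge compartment lookup tables
    by_edge: dict[int, list] = {}
    for c in model.compartments:
        by_edge.setdefault(c.branch_edge, []).append(c)
    soma_comp = model.soma_index

    for e, comps in by_edge.items():
        if e < 0:
            continue
        mask = edge_idx == e
        if not mask.any():
            continue
        starts = np.array([c.arc_start for c in comps])
        order = np.argsort(starts)
        starts = starts[order]
        idxs = np.array([comps[o].index for o in order])
        pos = np.searchsorted(starts, arc[mask], side="right") - 1
        pos = np.clip(pos, 0, len(idxs) - 1)
        labels[mask] = idxs[pos]
    on_soma = edge_idx == -1
    if on_soma.any():
        if soma_comp is not None:
            labels[on_soma] = soma_comp
        else:
            # no explicit soma compartment: hand to nearest compartment center
            from .mapping import build_index, nearest as nn_query
            idx = build_index(model.centers)
            win, _ = nn_query(idx, centroids[on_soma])
            labels[on_soma] = np.atleast_1d(win)
    labels[surface.region == REGION_OBSTACLE] = -1

    n_comp = len(model)
    areas = surface.triangle_areas()
    patch_areas = np.zeros(n_comp)
    valid = labels >= 0
    np.add.at(patch_areas, labels[valid], areas[valid])
    surface.patch_label = labels
    empty = np.nonzero(patch_areas == 0)[0]
    for i in empty:
        logger.warning("compartment %d has no membrane triangles", i)
    return labels, patch_areas, model.lateral_areas
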