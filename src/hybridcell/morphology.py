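"""Point-diameter neuron morphologies and the 1D compartment discretization.

A morphology is a tree of (position, radius) samples, as carried by the
community-standard SWC format or by the geometry subset of NEURON's hoc
dialect (``create``/``connect``/``pt3dadd``).  The tree is the shared
backbone of both representations used downstream: the 1D cylindrical
compartment model solved by :mod:`hybridcell.cable1d` and the 3D
surface/volume meshes generated by :mod:`hybridcell.meshgen`.

Units: positions and radii in um (SWC stores radii, hoc ``pt3dadd`` stores
diameters; both are converted on ingest).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (ConfigError, HocParseError, MorphologyStructureError,
                     SWCParseError)

logger = logging.getLogger(__name__)

SOMA = 1
DENDRITE = 3


@dataclass(frozen=True)
class MorphologyPoint:
    """One SWC-style sample: id, type code, position [um], radius [um]."""

    id: int
    type_code: int
    position: tuple[float, float, float]
    radius: float
    parent_id: int  # -1 for the root

    def __post_init__(self):
        if self.radius <= 0:
            raise MorphologyStructureError(
                f"point {self.id}: radius must be positive, got {self.radius}")
        if not np.all(np.isfinite(self.position)):
            raise MorphologyStructureError(
                f"point {self.id}: non-finite position {self.position}")


class MorphologyGraph:
    """A validated point-diameter tree.

    Points are stored in file order; internal indices are 0-based while the
    original SWC ids are preserved as metadata.  Edges are implied by parent
    links.
    """

    def __init__(self, points: list[MorphologyPoint]):
        self.points = list(points)
        self._validate()
        self.positions = np.array([p.position for p in self.points], float)
        self.radii = np.array([p.radius for p in self.points], float)
        self.type_codes = np.array([p.type_code for p in self.points], int)
        # 0-based parent index (-1 for root)
        id_to_idx = {p.id: i for i, p in enumerate(self.points)}
        self.parent_index = np.array(
            [-1 if p.parent_id == -1 else id_to_idx[p.parent_id]
             for p in self.points], int)

    # -- structure ---------------------------------------------------------

    def _validate(self):
        if not self.points:
            raise MorphologyStructureError("empty morphology")
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise MorphologyStructureError("duplicate point ids")
        id_set = set(ids)
        roots = [p for p in self.points if p.parent_id == -1]
        if len(roots) != 1:
            raise MorphologyStructureError(
                f"expected exactly one root, found {len(roots)}")
        for p in self.points:
            if p.parent_id != -1 and p.parent_id not in id_set:
                raise MorphologyStructureError(
                    f"point {p.id} references undefined parent {p.parent_id}")
            if p.parent_id != -1 and p.parent_id >= p.id:
                raise MorphologyStructureError(
                    f"point {p.id}: parent id {p.parent_id} must be smaller "
                    "than the point id")
        # cycle check: follow parent links from every node
        parent = {p.id: p.parent_id for p in self.points}
        for start in ids:
            seen = set()
            node = start
            while node != -1:
                if node in seen:
                    raise MorphologyStructureError(
                        f"cycle detected through point {node}")
                seen.add(node)
                node = parent[node]

    @property
    def root_index(self) -> int:
        return int(np.nonzero(self.parent_index == -1)[0][0])

    @property
    def n_points(self) -> int:
        return len(self.points)

    def edges(self) -> np.ndarray:
        """(n_edges, 2) array of 0-based (parent, child) index pairs."""
        child = np.nonzero(self.parent_index >= 0)[0]
        return np.column_stack([self.parent_index[child], child])

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in range(self.n_points)}
        for parent, child in self.edges():
            out[int(parent)].append(int(child))
        return out

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_points, int)
        for parent, child in self.edges():
            deg[parent] += 1
            deg[child] += 1
        return deg

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(
            self.positions[e[:, 1]] - self.positions[e[:, 0]], axis=1)

    def total_arc_length(self) -> float:
        return float(self.edge_lengths().sum())

    def soma_center_radius(self) -> tuple[np.ndarray, float] | None:
        """Bounding sphere of the type-1 samples, or None without a soma.

        A single soma sample is used as-is; multiple samples are enclosed in
        the smallest sphere centered at their centroid.
        """
        mask = self.type_codes == SOMA
        if not mask.any():
            return None
        pos = self.positions[mask]
        rad = self.radii[mask]
        if mask.sum() == 1:
            return pos[0], float(rad[0])
        center = pos.mean(axis=0)
        reach = np.linalg.norm(pos - center, axis=1) + rad
        return center, float(reach.max())

    # -- i/o ---------------------------------------------------------------

    def to_swc(self) -> str:
        """Canonical SWC serialization (stable byte-for-byte)."""
        lines = ["# generated by hybridcell"]
        for p in self.points:
            x, y, z = p.position
            lines.append(f"{p.id} {p.type_code} {x:.6f} {y:.6f} {z:.6f} "
                         f"{p.radius:.6f} {p.parent_id}")
        return "\n".join(lines) + "\n"

    def write_swc(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_swc())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MorphologyGraph):
            return NotImplemented
        return self.to_swc() == other.to_swc()


def read_swc(path) -> MorphologyGraph:
    """Read a standard 7-column SWC file.

    Column 6 is a *radius* and is stored as such.  Comment lines start
    with ``#``; blank lines are ignored.  Malformed lines raise
    :class:`SWCParseError` with the 1-based line number.
    """
    points: list[MorphologyPoint] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"expected 7 whitespace-separated fields, got "
                    f"{len(fields)}", lineno)
            try:
                pid = int(fields[0])
                tcode = int(fields[1])
                xyz = tuple(float(v) for v in fields[2:5])
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), lineno) from None
            if pid < 1:
                raise SWCParseError(f"point id must be >= 1, got {pid}",
                                    lineno)
            try:
                points.append(MorphologyPoint(pid, tcode, xyz, radius, parent))
            except MorphologyStructureError as exc:
                raise SWCParseError(str(exc), lineno) from None
    return MorphologyGraph(points)


# -- hoc geometry subset ----------------------------------------------------

_CREATE_RE = re.compile(r"^\s*create\s+(.+)$")
_CONNECT_RE = re.compile(
    r"^\s*connect\s+(\w+)\s*\(\s*([01])\s*\)\s*,\s*(\w+)\s*\(\s*([\d.]+)\s*\)")
_PT3DADD_RE = re.compile(
    r"(\w+)?\s*(?:\{)?\s*pt3dadd\s*\(\s*([-\d.eE]+)\s*,\s*([-\d.eE]+)\s*,"
    r"\s*([-\d.eE]+)\s*,\s*([-\d.eE]+)\s*\)")
_ACCESS_RE = re.compile(r"^\s*access\s+(\w+)")
_SECTION_BLOCK_RE = re.compile(r"^\s*(\w+)\s*\{")

_KNOWN_NOISE = ("insert", "forall", "psection", "nseg", "Ra", "cm", "L",
                "diam", "objref", "proc", "func", "}")


def read_hoc_subset(path) -> MorphologyGraph:
    """Read the geometry subset of a hoc file.

    Supported statements: ``create``, ``connect child(0|1), parent(x)`` and
    ``pt3dadd(x, y, z, diam)`` (inside a ``section {...}`` block or after
    ``access section``).  Anything else is ignored with a logged warning;
    hoc is treated purely as a geometry carrier.
    """
    sections: dict[str, list[tuple[float, float, float, float]]] = {}
    connections: list[tuple[str, int, str, float]] = []
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("//")[0].strip()
            if not line:
                continue
            m = _CREATE_RE.match(line)
            if m:
                for name in m.group(1).split(","):
                    name = name.strip()
                    if name:
                        sections.setdefault(name, [])
                continue
            m = _CONNECT_RE.match(line)
            if m:
                child, child_end, parent, parent_pos = (
                    m.group(1), int(m.group(2)), m.group(3),
                    float(m.group(4)))
                connections.append((child, child_end, parent, parent_pos))
                continue
            m = _ACCESS_RE.match(line)
            if m:
                current = m.group(1)
                sections.setdefault(current, [])
                continue
            m = _SECTION_BLOCK_RE.match(line)
            if m and m.group(1) in sections:
                current = m.group(1)
            matched_pt = False
            for m in _PT3DADD_RE.finditer(line):
                matched_pt = True
                sec = m.group(1) or current
                if sec is None or sec not in sections:
                    raise HocParseError(
                        f"line {lineno}: pt3dadd outside a known section")
                sections[sec].append(tuple(float(m.group(i))
                                           for i in range(2, 6)))
            if matched_pt or _SECTION_BLOCK_RE.match(line):
                continue
            if not line.startswith(_KNOWN_NOISE):
                logger.warning("hoc line %d ignored (unsupported): %s",
                               lineno, line)

    if not sections:
        raise HocParseError("no sections found")
    for child, _, parent, _ in connections:
        if parent not in sections:
            raise MorphologyStructureError(
                f"connect references undeclared section '{parent}'")
        if child not in sections:
            raise MorphologyStructureError(
                f"connect references undeclared section '{child}'")

    # assemble the tree: each section is a chain of points; connect wires
    # the child's first (or last) point to the parent's chosen endpoint.
    points: list[MorphologyPoint] = []
    first_id: dict[str, int] = {}
    last_id: dict[str, int] = {}
    next_id = 1
    child_of = {c: (p, pos, end) for c, end, p, pos in connections}
    # emit roots first, then children whose parent already has geometry
    ordered: list[str] = []
    remaining = list(sections)
    while remaining:
        progress = [s for s in remaining
                    if s not in child_of or child_of[s][0] in ordered]
        if not progress:
            raise MorphologyStructureError(
                f"unresolvable connect ordering among {remaining}")
        ordered.extend(progress)
        remaining = [s for s in remaining if s not in progress]
    for name in ordered:
        pts = sections[name]
        if not pts:
            logger.warning("section '%s' has no pt3dadd samples; skipped",
                           name)
            continue
        if name in child_of:
            pname, ppos, end = child_of[name]
            if pname not in last_id:
                raise MorphologyStructureError(
                    f"section '{name}' connected to '{pname}' which has no "
                    "geometry yet (out-of-order connect)")
            anchor = last_id[pname] if ppos >= 0.5 else first_id[pname]
            chain = pts if end == 0 else pts[::-1]
        else:
            anchor = -1
            chain = pts
        prev = anchor
        for x, y, z, diam in chain:
            tcode = SOMA if "soma" in name.lower() else DENDRITE
            points.append(MorphologyPoint(next_id, tcode, (x, y, z),
                                          diam / 2.0, prev))
            prev = next_id
            next_id += 1
        first_id[name] = next_id - len(chain)
        last_id[name] = next_id - 1
    return MorphologyGraph(points)


# -- compartments -----------------------------------------------------------

@dataclass
class Compartment:
    """One cylindrical compartment of the 1D discretization.

    ``diameter`` is the geometric (frustum mean) diameter; ``d_eff`` is the
    electrically effective diameter after obstacle correction and defaults
    to ``diameter``.
    """

    index: int
    proximal: np.ndarray
    distal: np.ndarray
    length: float
    diameter: float
    d_eff: float
    parent_index: int
    arc_start: float      # arc length from the branch origin [um]
    branch_edge: int      # index of the morphology edge this piece lies on

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.proximal + self.distal)

    @property
    def lateral_area(self) -> float:
        """Cylinder lateral area pi*d*l [um^2]."""
        return float(np.pi * self.diameter * self.length)


class CompartmentModel:
    """Ordered collection of compartments partitioning the morphology."""

    def __init__(self, compartments: list[Compartment],
                 graph: MorphologyGraph, soma_index: int | None = None):
        self.compartments = compartments
        self.graph = graph
        self.soma_index = soma_index

    def __len__(self):
        return len(self.compartments)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.compartments])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.compartments])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.compartments])

    @property
    def d_eff(self) -> np.ndarray:
        return np.array([c.d_eff for c in self.compartments])

    @property
    def lateral_areas(self) -> np.ndarray:
        return np.array([c.lateral_area for c in self.compartments])

    @property
    def parent_indices(self) -> np.ndarray:
        return np.array([c.parent_index for c in self.compartments])

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def total_lateral_area(self) -> float:
        return float(self.lateral_areas.sum())

    def stimulation_default(self) -> int:
        """Default current-clamp site: soma if present, else the middle
        compartment (the protocol inserts the electrode at the soma mid)."""
        if self.soma_index is not None:
            return self.soma_index
        return len(self.compartments) // 2


def build_compartments(graph: MorphologyGraph,
                       max_length: float) -> CompartmentModel:
    """Split every morphology edge into cylinders of length <= max_length.

    Each edge (a frustum between two samples) is cut into
    ``ceil(L/max_length)`` equal pieces; each piece is a cylinder with the
    frustum's mean diameter at the piece midpoint.  A spherical soma root
    becomes a single equivalent cylinder with l = d = 2r (same membrane
    area as the sphere).
    """
    if max_length <= 0:
        raise ConfigError("max_length must be positive")
    comps: list[Compartment] = []
    soma_index = None
    # last compartment index generated for each graph point
    tail_comp: dict[int, int] = {}

    root = graph.root_index
    soma = graph.soma_center_radius()
    if soma is not None and graph.type_codes[root] == SOMA:
        center, radius = soma
        axis = np.array([2 * radius, 0.0, 0.0])
        comps.append(Compartment(
            index=0, proximal=center - axis / 2, distal=center + axis / 2,
            length=2 * radius, diameter=2 * radius, d_eff=2 * radius,
            parent_index=-1, arc_start=0.0, branch_edge=-1))
        soma_index = 0
        tail_comp[root] = 0
    else:
        tail_comp[root] = -1

    # walk edges in parent-before-child order (guaranteed acyclic)
    order = edge_order(graph)
    for edge_idx, (pi, ci) in enumerate(order):
        if graph.type_codes[ci] == SOMA and soma_index is not None and \
                pi == root:
            # extra soma samples are folded into the soma sphere
            tail_comp[ci] = tail_comp[root]
            continue
        a = graph.positions[pi]
        b = graph.positions[ci]
        length = float(np.linalg.norm(b - a))
        if length == 0:
            tail_comp[ci] = tail_comp.get(pi, -1)
            continue
        n_pieces = max(1, int(np.ceil(length / max_length - 1e-12)))
        piece_len = length / n_pieces
        d_a, d_b = 2 * graph.radii[pi], 2 * graph.radii[ci]
        parent = tail_comp.get(pi, -1)
        for j in range(n_pieces):
            t0, t1 = j / n_pieces, (j + 1) / n_pieces
            tm = 0.5 * (t0 + t1)
            diam = d_a + (d_b - d_a) * tm
            comp = Compartment(
                index=len(comps),
                proximal=a + (b - a) * t0,
                distal=a + (b - a) * t1,
                length=piece_len, diameter=diam, d_eff=diam,
                parent_index=parent, arc_start=t0 * length,
                branch_edge=edge_idx)
            comps.append(comp)
            parent = comp.index
        tail_comp[ci] = parent
    return CompartmentModel(comps, graph, soma_index)


def edge_order(graph: MorphologyGraph):
    """Edges in deterministic parent-before-child order; the shared
    edge indexing used by compartments, obstacles and the mesh generator."""
    children = graph.children()
    order = []
    stack = [graph.root_index]
    edge_list = {(int(p), int(c)) for p, c in graph.edges()}
    while stack:
        node = stack.pop()
        for ch in sorted(children[node]):
            if (node, ch) in edge_list:
                order.append((node, ch))
            stack.append(ch)
    return order


# -- synthetic morphologies --------------------------------------------------

def generate_synthetic(kind: str, seed: int = 0, **dims) -> MorphologyGraph:
    """Deterministic toy morphologies used throughout the test protocols.

    ``cylinder``  -- a straight dendrite (length, radius, n_points)
    ``y_branch``  -- stem plus two diverging daughters (one bifurcation)
    ``soma_tree`` -- spherical soma with >= 2 dendrites (exercises the
                     soma-meshing path); dendrite directions drawn from the
                     seeded generator.

    These fixtures stand in for published reconstructions; the same seed
    always yields a byte-identical SWC serialization.
    """
    kind = kind.lower()
    if kind == "cylinder":
        length = float(dims.get("length", 10.0))
        radius = float(dims.get("radius", 1.0))
        n_points = int(dims.get("n_points", 2))
        if length <= 0 or radius <= 0 or n_points < 2:
            raise ConfigError("cylinder needs positive dims, n_points >= 2")
        xs = np.linspace(0.0, length, n_points)
        pts = [MorphologyPoint(1, DENDRITE, (0.0, 0.0, 0.0), radius, -1)]
        for i, x in enumerate(xs[1:], start=2):
            pts.append(MorphologyPoint(i, DENDRITE, (float(x), 0.0, 0.0),
                                       radius, i - 1))
        return MorphologyGraph(pts)

    if kind == "y_branch":
        stem = float(dims.get("stem_length", 8.0))
        branch = float(dims.get("branch_length", 6.0))
        radius = float(dims.get("radius", 1.0))
        child_radius = float(dims.get("child_radius", 0.8 * radius))
        half_angle = float(dims.get("half_angle_deg", 30.0)) * np.pi / 180
        if min(stem, branch, radius) <= 0:
            raise ConfigError("y_branch needs positive dims")
        c, s = np.cos(half_angle), np.sin(half_angle)
        pts = [
            MorphologyPoint(1, DENDRITE, (0.0, 0.0, 0.0), radius, -1),
            MorphologyPoint(2, DENDRITE, (stem, 0.0, 0.0), radius, 1),
            MorphologyPoint(3, DENDRITE,
                            (stem + branch * c, branch * s, 0.0),
                            child_radius, 2),
            MorphologyPoint(4, DENDRITE,
                            (stem + branch * c, -branch * s, 0.0),
                            child_radius, 2),
        ]
        return MorphologyGraph(pts)

    if kind == "soma_tree":
        soma_radius = float(dims.get("soma_radius", 3.0))
        n_dend = int(dims.get("n_dendrites", 3))
        dend_length = float(dims.get("dendrite_length", 8.0))
        dend_radius = float(dims.get("dendrite_radius", 0.8))
        if n_dend < 2:
            raise ConfigError("soma_tree needs >= 2 dendrites")
        rng = np.random.default_rng(seed)
        pts = [MorphologyPoint(1, SOMA, (0.0, 0.0, 0.0), soma_radius, -1)]
        next_id = 2
        # evenly spread base directions, jittered deterministically
        for k in range(n_dend):
            phi = 2 * np.pi * k / n_dend + rng.uniform(-0.2, 0.2)
            theta = np.pi / 2 + rng.uniform(-0.5, 0.5)
            u = np.array([np.cos(phi) * np.sin(theta),
                          np.sin(phi) * np.sin(theta), np.cos(theta)])
            base = 0.9 * soma_radius * u
            tip = base + dend_length * u
            pts.append(MorphologyPoint(next_id, DENDRITE,
                                       tuple(np.round(base, 6)),
                                       dend_radius, 1))
            pts.append(MorphologyPoint(next_id + 1, DENDRITE,
                                       tuple(np.round(tip, 6)),
                                       dend_radius, next_id))
            next_id += 2
        return MorphologyGraph(pts)

    raise ConfigError(f"unknown synthetic morphology kind '{kind}'")
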