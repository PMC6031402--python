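"""Polygonal keratinocyte tissue and its vertex graph.

Basal keratinocytes (Kcs) are modeled as convex polygons that partition a
square field of embryonic epidermis.  The polygons are the Voronoi cells of
a random point set, clipped to the square; melanoblasts live on the polygon
*vertices* and hop along polygon *edges*, so the tissue is exposed both as a
polygon list and as a planar graph (nodes, edges, adjacency).

The clipping uses the classical mirror trick: reflecting the seed points
across the four sides of the square makes every original point's Voronoi
cell bounded, with cell boundaries lying exactly on the square's sides, so
the cells of the original points tile the square without a separate
polygon-clipping pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import Voronoi, cKDTree

__all__ = ["DomainSpec", "Tissue", "build_tissue", "mean_edge_length", "nodes_within_depth"]


@dataclass(frozen=True)
class DomainSpec:
    """Square tissue domain: side length in micrometres, target Kc count, RNG seed."""

    side_length: float
    n_kcs: int
    seed: int = 0
    lloyd_iterations: int = 0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.n_kcs < 1:
            raise ValueError("n_kcs must be >= 1")
        if self.lloyd_iterations < 0:
            raise ValueError("lloyd_iterations must be >= 0")


@dataclass
class Tissue:
    """A polygonal Kc tiling of a square and its vertex/edge graph.

    Coordinates are continuous 2-D positions in micrometres with the origin at
    the square's lower-left corner.  Polygon rings are counterclockwise.
    """

    side_length: float
    node_coords: np.ndarray            # (n_nodes, 2) float
    polygons: list[np.ndarray]         # per-Kc ordered vertex-index ring, CCW
    edges: np.ndarray                  # (n_edges, 2) int, each row sorted
    node_adjacency: list[np.ndarray]   # per-node neighbor node indices
    node_kcs: list[np.ndarray]         # per-node incident Kc indices
    kc_perimeter: np.ndarray           # (n_kcs,) float, um

    _node_kc_mat: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)
    _adj_mean_mat: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_kcs(self) -> int:
        return len(self.polygons)

    def edge_lengths(self) -> np.ndarray:
        a, b = self.edges[:, 0], self.edges[:, 1]
        return np.linalg.norm(self.node_coords[a] - self.node_coords[b], axis=1)

    def kc_areas(self) -> np.ndarray:
        """Shoelace area of each Kc polygon."""
        areas = np.empty(self.n_kcs)
        for k, ring in enumerate(self.polygons):
            p = self.node_coords[ring]
            x, y = p[:, 0], p[:, 1]
            areas[k] = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return areas

    def nodes_within_depth(self, node: int, depth: int) -> set[int]:
        """Breadth-first neighborhood of graph distance <= depth, excluding `node`."""
        if not 0 <= node < self.n_nodes:
            raise IndexError(f"node index {node} out of range")
        if depth < 0:
            raise ValueError("depth must be >= 0")
        seen = {node}
        frontier = [node]
        out: set[int] = set()
        for _ in range(depth):
            nxt = []
            for u in frontier:
                for v in self.node_adjacency[u]:
                    if v not in seen:
                        seen.add(v)
                        out.add(v)
                        nxt.append(v)
            frontier = nxt
        return out

    # -- cached sparse operators used by the potential field ------------------

    @property
    def node_kc_matrix(self) -> sparse.csr_matrix:
        """Row-normalized (n_nodes x n_kcs) incidence; phi_A = M @ psi."""
        if self._node_kc_mat is None:
            rows, cols, vals = [], [], []
            for n, kcs in enumerate(self.node_kcs):
                w = 1.0 / len(kcs)
                for k in kcs:
                    rows.append(n)
                    cols.append(k)
                    vals.append(w)
            self._node_kc_mat = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n_nodes, self.n_kcs)
            )
        return self._node_kc_mat

    @property
    def adjacency_mean_matrix(self) -> sparse.csr_matrix:
        """Row-normalized (n_nodes x n_nodes) adjacency; averages over neighbors."""
        if self._adj_mean_mat is None:
            rows, cols, vals = [], [], []
            for n, nbrs in enumerate(self.node_adjacency):
                w = 1.0 / len(nbrs)
                for m in nbrs:
                    rows.append(n)
                    cols.append(m)
                    vals.append(w)
            self._adj_mean_mat = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
            )
        return self._adj_mean_mat

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "side_length": self.side_length,
            "node_coords": self.node_coords.tolist(),
            "polygons": [ring.tolist() for ring in self.polygons],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Tissue":
        doc = json.loads(text)
        coords = np.asarray(doc["node_coords"], dtype=float)
        rings = [np.asarray(r, dtype=np.intp) for r in doc["polygons"]]
        return _assemble(doc["side_length"], coords, rings)


def _assemble(side: float, coords: np.ndarray, rings: list[np.ndarray]) -> Tissue:
    """Derive edges, adjacency, node->Kc incidence and perimeters from rings."""
    n_nodes = len(coords)
    edge_set: set[tuple[int, int]] = set()
    node_kcs: list[list[int]] = [[] for _ in range(n_nodes)]
    for k, ring in enumerate(rings):
        for idx, a in enumerate(ring):
            b = ring[(idx + 1) % len(ring)]
            edge_set.add((min(a, b), max(a, b)))
            node_kcs[a].append(k)
    edges = np.array(sorted(edge_set), dtype=np.intp).reshape(-1, 2)
    adj: list[set[int]] = [set() for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    node_adjacency = [np.array(sorted(s), dtype=np.intp) for s in adj]
    node_kcs_arr = [np.array(sorted(set(ks)), dtype=np.intp) for ks in node_kcs]
    perims = np.empty(len(rings))
    for k, ring in enumerate(rings):
        p = coords[ring]
        perims[k] = np.linalg.norm(p - np.roll(p, -1, axis=0), axis=1).sum()
    return Tissue(
        side_length=side,
        node_coords=coords,
        polygons=rings,
        edges=edges,
        node_adjacency=node_adjacency,
        node_kcs=node_kcs_arr,
        kc_perimeter=perims,
    )


def _mirror(points: np.ndarray, side: float) -> np.ndarray:
    """Original points followed by their reflections across the four sides."""
    left = points * [-1, 1]
    right = points * [-1, 1] + [2 * side, 0]
    down = points * [1, -1]
    up = points * [1, -1] + [0, 2 * side]
    return np.vstack([points, left, right, down, up])


def _dedupe_points(points: np.ndarray, side: float, rng: np.random.Generator) -> np.ndarray:
    """Jitter seed points that coincide within 1e-9*side (degenerate Voronoi input)."""
    tol = 1e-9 * side
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if len(pairs):
        dup = np.unique(pairs[:, 1])
        points = points.copy()
        points[dup] += rng.uniform(-1e-6 * side, 1e-6 * side, size=(len(dup), 2))
        points = np.clip(points, 1e-9 * side, side * (1 - 1e-9))
    return points


def _voronoi_cells(points: np.ndarray, side: float) -> list[np.ndarray]:
    """CCW coordinate rings of the square-clipped Voronoi cells of `points`."""
    vor = Voronoi(_mirror(points, side))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        assert -1 not in region, "mirrored Voronoi cell should be bounded"
        ring = vor.vertices[region]
        # shoelace orientation; make CCW
        x, y = ring[:, 0], ring[:, 1]
        if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
            ring = ring[::-1]
        cells.append(ring)
    return cells


def build_tissue(spec: DomainSpec) -> Tissue:
    """Build the Voronoi-like Kc tiling of the square for a domain spec.

    Deterministic for a fixed seed.  Degenerate (duplicate) seed points are
    jittered rather than rejected.  Optional Lloyd relaxation iterations
    regularize the cell-size distribution.
    """
    side = float(spec.side_length)
    if spec.n_kcs == 1:
        coords = np.array([[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]])
        return _assemble(side, coords, [np.arange(4, dtype=np.intp)])

    rng = np.random.default_rng(spec.seed)
    points = rng.uniform(0.0, side, size=(spec.n_kcs, 2))
    points = _dedupe_points(points, side, rng)

    for _ in range(spec.lloyd_iterations):
        cells = _voronoi_cells(points, side)
        for i, ring in enumerate(cells):
            x, y = ring[:, 0], ring[:, 1]
            cross = x * np.roll(y, -1) - np.roll(x, -1) * y
            area = 0.5 * cross.sum()
            cx = np.sum((x + np.roll(x, -1)) * cross) / (6 * area)
            cy = np.sum((y + np.roll(y, -1)) * cross) / (6 * area)
            points[i] = (cx, cy)
        points = _dedupe_points(np.clip(points, 0, side), side, rng)

    cells = _voronoi_cells(points, side)

    # Merge coincident vertices across cells into shared graph nodes.
    all_pts = np.vstack(cells)
    tol = 1e-9 * side
    # snap vertices that lie on the square boundary exactly onto it
    for axis in (0, 1):
        for bound in (0.0, side):
            on = np.abs(all_pts[:, axis] - bound) < 1e-7 * side
            all_pts[on, axis] = bound
    tree = cKDTree(all_pts)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(all_pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(len(all_pts))])
    uniq_roots, node_of = np.unique(roots, return_inverse=True)
    coords = all_pts[uniq_roots]

    rings: list[np.ndarray] = []
    offset = 0
    for ring_pts in cells:
        m = len(ring_pts)
        idx = node_of[offset : offset + m]
        offset += m
        # drop consecutive duplicates produced by merging
        keep = [j for j in range(m) if idx[j] != idx[(j + 1) % m]]
        rings.append(np.asarray(idx[keep], dtype=np.intp))
    return _assemble(side, coords, rings)


def mean_edge_length(tissue: Tissue) -> float:
    """Arithmetic mean of all unique polygon-edge lengths (um)."""
    lengths = tissue.edge_lengths()
    if len(lengths) == 0:
        raise ValueError("tissue has no edges")
    return float(lengths.mean())


def nodes_within_depth(tissue: Tissue, node: int, depth: int) -> set[int]:
    """Graph neighborhood of `node` within `depth` hops (excluding itself)."""
    return tissue.nodes_within_depth(node, depth)
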