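"""Vessel graph construction from vascular template images.

Converts binary/grayscale vascular templates into directed, velocity-annotated
vessel graphs: adaptive-threshold segmentation, medial-axis skeletonization,
skeleton-to-graph conversion, BFS orientation, and reference-velocity
assignment from radius-velocity statistics or from an aligned velocity map.
Also provides a synthetic branching-template generator so the full pipeline is
testable without external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import draw as _skdraw
from skimage import filters as _skfilters
from skimage import morphology as _skmorph

__all__ = [
    "VesselMask",
    "SkeletonMap",
    "VesselGraph",
    "RadiusVelocityTable",
    "segment_vessels",
    "skeletonize_mask",
    "build_undirected_graph",
    "orient_graph",
    "build_radius_velocity_table",
    "assign_reference_velocity",
    "assign_velocity_from_map",
    "synthetic_vessel_template",
    "save_graph",
    "load_graph",
]

#: floor (px/frame) applied to drawn centerline velocities
VELOCITY_FLOOR = 0.01

#: skeleton spurs shorter than this many pixels are pruned
MIN_EDGE_LENGTH = 3


@dataclass
class VesselMask:
    """Binary vessel mask with isotropic pixel calibration (micrometres)."""

    grid: np.ndarray
    pixel_size: float = 4.9

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class SkeletonMap:
    """One-pixel-wide medial axis plus local half-width from the EDT."""

    skeleton: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=bool)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.skeleton.shape != self.radius.shape:
            raise ValueError("skeleton and radius maps must share a shape")


@dataclass(eq=False)
class Edge:
    """A vessel segment: ordered pixel path with per-point radii."""

    u: tuple[int, int]
    v: tuple[int, int]
    path: np.ndarray  # (n, 2) int array of (row, col)
    radii: np.ndarray  # (n,) float
    v_ref: float = 0.0

    @property
    def length(self) -> float:
        """Geometric polyline length in pixels."""
        if len(self.path) < 2:
            return 0.0
        d = np.diff(self.path.astype(float), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def volume(self) -> float:
        """a_e = sum over path points of pi * r_i**2."""
        return float(np.pi * np.square(self.radii).sum())

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    def arclengths(self) -> np.ndarray:
        """Cumulative arc length at each path point, starting at 0."""
        if len(self.path) < 2:
            return np.zeros(len(self.path))
        d = np.diff(self.path.astype(float), axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])

    def radius_at(self, s: float) -> float:
        """Local radius at arc length ``s``, linearly interpolated."""
        cs = self.arclengths()
        return float(np.interp(s, cs, self.radii))

    def point_at(self, s: float) -> np.ndarray:
        """(row, col) position at arc length ``s``."""
        cs = self.arclengths()
        r = np.interp(s, cs, self.path[:, 0].astype(float))
        c = np.interp(s, cs, self.path[:, 1].astype(float))
        return np.array([r, c])

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent (d_row, d_col) at arc length ``s``."""
        cs = self.arclengths()
        if cs[-1] == 0:
            return np.array([0.0, 1.0])
        i = int(np.clip(np.searchsorted(cs, s, side="right") - 1, 0, len(cs) - 2))
        d = self.path[i + 1].astype(float) - self.path[i].astype(float)
        n = np.hypot(*d)
        return d / n if n > 0 else np.array([0.0, 1.0])


class VesselGraph:
    """Directed forest of vessel segments over a pixel grid.

    Vertices are (row, col) skeleton junctions/endpoints; edges carry ordered
    point paths, per-point radii, and a centerline reference velocity.
    """

    def __init__(self, shape: tuple[int, int], directed: bool = False):
        self.shape = tuple(shape)
        self.directed = directed
        self.graph: nx.MultiGraph = nx.MultiDiGraph() if directed else nx.MultiGraph()
        self.edges: list[Edge] = []

    def add_edge(self, edge: Edge) -> int:
        eid = len(self.edges)
        self.edges.append(edge)
        self.graph.add_node(edge.u)
        self.graph.add_node(edge.v)
        self.graph.add_edge(edge.u, edge.v, key=eid, eid=eid)
        return eid

    def add_vertex(self, v: tuple[int, int]) -> None:
        self.graph.add_node(v)

    @property
    def vertices(self) -> list[tuple[int, int]]:
        return list(self.graph.nodes)

    @property
    def total_volume(self) -> float:
        """A = sum of a_e over all edges."""
        return float(sum(e.volume for e in self.edges))

    def outgoing(self, vertex: tuple[int, int]) -> list[int]:
        """Edge ids leaving ``vertex`` (directed graphs only)."""
        if not self.directed:
            raise ValueError("outgoing() requires an oriented graph")
        return [d["eid"] for _, _, d in self.graph.out_edges(vertex, data=True)]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class RadiusVelocityTable:
    """(radius px, velocity) pairs sorted ascending by radius."""

    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        order = np.argsort(self.pairs[:, 0], kind="stable")
        self.pairs = self.pairs[order]
        if len(self.pairs) and self.pairs[:, 0].min() < 0:
            raise ValueError("radii must be non-negative")

    @property
    def radii(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def velocities(self) -> np.ndarray:
        return self.pairs[:, 1]

    def window(self, d: float, half_width: float = 0.5) -> np.ndarray:
        """Velocities of pairs with radius within ``d +/- half_width``."""
        sel = np.abs(self.radii - d) <= half_width
        return self.velocities[sel]

    def nearest(self, d: float) -> float:
        """Velocity of the pair whose radius is closest to ``d``."""
        if not len(self.pairs):
            raise ValueError("empty table")
        return float(self.velocities[np.argmin(np.abs(self.radii - d))])


# ---------------------------------------------------------------------------
# segmentation & skeletonization
# ---------------------------------------------------------------------------


def segment_vessels(
    image: np.ndarray,
    block_size: int = 51,
    offset: float = 0.0,
    dark_vessels: bool = False,
    pixel_size: float = 4.9,
) -> VesselMask:
    """Adaptive-threshold binarization of a single-channel vascular image.

    A pixel is foreground when it exceeds (or, for ``dark_vessels``, falls
    below) the local-mean threshold of its ``block_size`` neighbourhood minus
    ``offset``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be single-channel 2-D (extract green channel first)")
    if block_size % 2 == 0 or block_size < 3:
        raise ValueError("block_size must be an odd integer >= 3")
    thresh = _skfilters.threshold_local(image, block_size=block_size, method="mean", offset=offset)
    grid = image < thresh if dark_vessels else image > thresh
    if not grid.any():
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
    return VesselMask(grid=grid, pixel_size=pixel_size)


def skeletonize_mask(mask: VesselMask) -> SkeletonMap:
    """Medial-axis skeleton plus Euclidean-distance-transform radii."""
    if not mask.grid.any():
        raise ValueError("cannot skeletonize an empty mask")
    # fixed rng: medial_axis breaks pixel ties randomly otherwise
    skel, dist = _skmorph.medial_axis(mask.grid, return_distance=True, rng=0)
    radius = np.where(skel, dist, 0.0)
    return SkeletonMap(skeleton=skel, radius=radius)


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbors(skel: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
    h, w = skel.shape
    out = []
    for dr, dc in _NBRS:
        r, c = p[0] + dr, p[1] + dc
        if 0 <= r < h and 0 <= c < w and skel[r, c]:
            out.append((r, c))
    return out


def build_undirected_graph(
    skel: SkeletonMap, min_edge_length: int = MIN_EDGE_LENGTH
) -> VesselGraph:
    """Convert a skeleton into an undirected vessel graph.

    Vertices are skeleton pixels with a number of skeleton neighbours other
    than 2 (endpoints and junctions); edges are maximal paths between vertices
    carrying per-point radii. Isolated cycles become one self-loop edge with a
    single designated vertex. Spur edges shorter than ``min_edge_length``
    path pixels that end at a degree-1 vertex are pruned.
    """
    skeleton = skel.skeleton
    if not skeleton.any():
        raise ValueError("empty skeleton")
    g = VesselGraph(shape=skeleton.shape, directed=False)

    nbr_count = _neighbor_count(skeleton)
    is_vertex = skeleton & (nbr_count != 2)

    visited = np.zeros_like(skeleton, dtype=bool)
    vertices = list(zip(*np.nonzero(is_vertex)))
    vset = set(vertices)
    seen_vv: set = set()  # de-dupes directly adjacent vertex pairs

    # trace maximal paths starting at each vertex
    for v in vertices:
        for n in _neighbors(skeleton, v):
            if visited[n] and n not in vset:
                continue
            path = _trace_path(skeleton, visited, vset, seen_vv, v, n)
            if path is None:
                continue
            _add_path_edge(g, skel, path, min_edge_length)

    # remaining unvisited pixels with all-degree-2 belong to isolated cycles
    remaining = skeleton & ~visited & ~is_vertex
    for r, c in zip(*np.nonzero(remaining)):
        if visited[r, c]:
            continue
        cycle = _trace_cycle(skeleton, visited, (r, c))
        if cycle is not None:
            _add_path_edge(g, skel, cycle, min_edge_length=0)

    # isolated vertex pixels (single points) are kept as bare vertices
    for v in vertices:
        if v not in g.graph:
            g.add_vertex(v)
    return g


def _neighbor_count(skeleton: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skeleton.astype(int), kernel, mode="constant")


def _trace_path(skeleton, visited, vset, seen_vv, v, start):
    """Walk from vertex ``v`` through ``start`` until hitting another vertex."""
    if start in vset:  # direct vertex-vertex adjacency
        key = (min(v, start), max(v, start))
        if key in seen_vv:
            return None
        seen_vv.add(key)
        return [v, start]
    path = [v, start]
    visited[start] = True
    prev, cur = v, start
    while True:
        nbrs = [n for n in _neighbors(skeleton, cur) if n != prev]
        term = [n for n in nbrs if n in vset]
        interior = [n for n in nbrs if n not in vset and not visited[n]]
        if term:
            path.append(term[0])
            return path
        if not interior:
            return path  # dead end (shouldn't happen on clean skeletons)
        cur2 = interior[0]
        visited[cur2] = True
        path.append(cur2)
        prev, cur = cur, cur2


def _trace_cycle(skeleton, visited, start):
    """Trace an isolated all-degree-2 cycle starting anywhere on it."""
    path = [start]
    visited[start] = True
    prev, cur = None, start
    while True:
        nbrs = [n for n in _neighbors(skeleton, cur) if n != prev]
        unvis = [n for n in nbrs if not visited[n]]
        if not unvis:
            # close the loop back to start
            if start in nbrs and len(path) > 2:
                path.append(start)
            return path if len(path) > 2 else None
        nxt = unvis[0]
        visited[nxt] = True
        path.append(nxt)
        prev, cur = cur, nxt


def _add_path_edge(g: VesselGraph, skel: SkeletonMap, path, min_edge_length: int):
    path_arr = np.array(path, dtype=int)
    radii = np.maximum(skel.radius[path_arr[:, 0], path_arr[:, 1]], 0.5)
    u, v = tuple(path[0]), tuple(path[-1])
    # prune short spurs: short edge ending at an endpoint of the skeleton
    if len(path) < min_edge_length and u != v:
        deg_u = len(_neighbors(skel.skeleton, u))
        deg_v = len(_neighbors(skel.skeleton, v))
        if deg_u == 1 or deg_v == 1:
            return
    g.add_edge(Edge(u=u, v=v, path=path_arr, radii=radii))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def orient_graph(g: VesselGraph) -> VesselGraph:
    """Assign flow directions via BFS spanning trees, one per component.

    Source per component: the degree-1 vertex with the largest local radius
    (lexicographic smallest coordinate breaks ties); for components without
    degree-1 vertices the vertex with the largest radius. Tree edges point
    from earlier- to later-visited vertex; non-tree edges (including
    self-loops) are discarded, so the result is a forest.
    """
    if g.directed:
        raise ValueError("graph is already oriented")
    out = VesselGraph(shape=g.shape, directed=True)
    vertex_radius = _vertex_radii(g)

    for comp in nx.connected_components(g.graph):
        sub = g.graph.subgraph(comp)
        deg1 = [v for v in comp if sub.degree(v) == 1]
        pool = deg1 if deg1 else list(comp)
        source = max(pool, key=lambda v: (vertex_radius.get(v, 0.0), (-v[0], -v[1])))
        order = {source: 0}
        queue = [source]
        tree_edges = []
        while queue:
            u = queue.pop(0)
            for _, w, k, d in sorted(sub.edges(u, keys=True, data=True), key=lambda t: t[2]):
                if w not in order:
                    order[w] = len(order)
                    queue.append(w)
                    tree_edges.append((u, w, d["eid"]))
        for u, w, eid in tree_edges:
            e = g.edges[eid]
            path, radii = e.path, e.radii
            if tuple(path[0]) != u:  # flip path so it runs source -> sink
                path, radii = path[::-1].copy(), radii[::-1].copy()
            out.add_edge(Edge(u=u, v=w, path=path, radii=radii, v_ref=e.v_ref))
        if not tree_edges:
            out.add_vertex(source)
    return out


def _vertex_radii(g: VesselGraph) -> dict:
    rad: dict = {}
    for e in g.edges:
        for vert, r in ((e.u, e.radii[0]), (e.v, e.radii[-1])):
            rad[vert] = max(rad.get(vert, 0.0), float(r))
    return rad


# ---------------------------------------------------------------------------
# velocity assignment
# ---------------------------------------------------------------------------


def build_radius_velocity_table(
    velocity_map: np.ndarray, pixel_size: float = 4.9
) -> RadiusVelocityTable:
    """Collect (radius, velocity) pairs on the medial axis of a velocity map.

    The map is binarized (nonzero = vessel), medial-axis skeletonized, and
    each skeleton pixel contributes its EDT radius and map velocity. Pairs are
    sorted ascending by radius.
    """
    velocity_map = np.asarray(velocity_map, dtype=float)
    if (velocity_map < 0).any():
        raise ValueError("velocity map must be non-negative")
    mask = velocity_map > 0
    if not mask.any():
        raise ValueError("all-zero velocity map: no radius-velocity pairs")
    skel, dist = _skmorph.medial_axis(mask, return_distance=True, rng=0)
    rr, cc = np.nonzero(skel)
    pairs = np.column_stack([dist[rr, cc], velocity_map[rr, cc]])
    return RadiusVelocityTable(pairs=pairs)


def assign_reference_velocity(
    g: VesselGraph,
    table: RadiusVelocityTable,
    rng_seed: int | np.random.Generator = 0,
    window_half_width: float = 0.5,
) -> VesselGraph:
    """Draw per-edge centerline velocities from N(mu, sigma^2).

    For an edge of mean radius d, mu and sigma^2 are the mean and variance of
    table velocities with radius within d +/- ``window_half_width``; empty
    windows fall back to the nearest-radius pair with sigma = 0. Draws are
    clipped below at a small positive floor.
    """
    if not g.directed:
        raise ValueError("orient the graph before assigning velocities")
    if not len(table.pairs):
        raise ValueError("empty radius-velocity table")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    for e in g.edges:
        d = e.mean_radius
        vels = table.window(d, window_half_width)
        if len(vels) == 0:
            mu, sigma = table.nearest(d), 0.0
        else:
            mu, sigma = float(vels.mean()), float(vels.std())
        v = mu if sigma == 0 else float(rng.normal(mu, sigma))
        e.v_ref = max(v, VELOCITY_FLOOR)
    return g


def assign_velocity_from_map(
    g: VesselGraph,
    velocity_map: np.ndarray,
    fallback_table: RadiusVelocityTable | None = None,
) -> VesselGraph:
    """Set each edge's v_ref to the mean nonzero map value in its footprint.

    The footprint is the edge path dilated by the local radius. Edges whose
    footprint holds no nonzero pixels take the nearest-radius velocity from
    ``fallback_table`` (or the velocity floor if no table is given).
    """
    if not g.directed:
        raise ValueError("orient the graph before assigning velocities")
    velocity_map = np.asarray(velocity_map, dtype=float)
    if velocity_map.shape != tuple(g.shape):
        raise ValueError(
            f"velocity map shape {velocity_map.shape} != graph frame {g.shape}"
        )
    h, w = g.shape
    for e in g.edges:
        vals = []
        for (r, c), rad in zip(e.path, e.radii):
            ri = int(np.ceil(rad))
            r0, r1 = max(0, r - ri), min(h, r + ri + 1)
            c0, c1 = max(0, c - ri), min(w, c + ri + 1)
            patch = velocity_map[r0:r1, c0:c1]
            yy, xx = np.mgrid[r0:r1, c0:c1]
            sel = ((yy - r) ** 2 + (xx - c) ** 2 <= rad**2) & (patch > 0)
            vals.append(patch[sel])
        vals = np.concatenate(vals) if vals else np.array([])
        if vals.size:
            e.v_ref = float(vals.mean())
        elif fallback_table is not None and len(fallback_table.pairs):
            e.v_ref = max(fallback_table.nearest(e.mean_radius), VELOCITY_FLOOR)
        else:
            e.v_ref = VELOCITY_FLOOR
    return g


# ---------------------------------------------------------------------------
# synthetic templates
# ---------------------------------------------------------------------------


def synthetic_vessel_template(
    width: int,
    height: int,
    n_trees: int = 2,
    radius_range: tuple[float, float] = (2.0, 6.0),
    tortuosity: float = 0.15,
    rng_seed: int | np.random.Generator = 0,
    branch_prob: float = 0.03,
    pixel_size: float = 4.9,
) -> VesselMask:
    """Render random branching vascular trees as a binary mask.

    Centerlines are random walks with curvature scale ``tortuosity``; radii
    taper from ``radius_range[1]`` toward ``radius_range[0]``; bifurcations
    spawn 1-2 children. Deterministic for a fixed seed.
    """
    r_min, r_max = radius_range
    if not (0 < r_min <= r_max):
        raise ValueError("radius_range must satisfy 0 < min <= max")
    if r_max >= min(width, height) / 4:
        raise ValueError("radius_range too large for the grid")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    grid = np.zeros((height, width), dtype=bool)

    for _ in range(n_trees):
        # root on a border, heading inward
        side = rng.integers(4)
        if side == 0:
            pos = np.array([0.0, rng.uniform(0.2, 0.8) * width])
            theta = np.pi / 2
        elif side == 1:
            pos = np.array([height - 1.0, rng.uniform(0.2, 0.8) * width])
            theta = -np.pi / 2
        elif side == 2:
            pos = np.array([rng.uniform(0.2, 0.8) * height, 0.0])
            theta = 0.0
        else:
            pos = np.array([rng.uniform(0.2, 0.8) * height, width - 1.0])
            theta = np.pi
        stack = [(pos, theta, float(rng.uniform(0.75 * r_max, r_max)), 0)]
        while stack:
            pos, theta, radius, depth = stack.pop()
            pos = pos.copy()
            n_steps = int(rng.integers(20, max(21, (width + height) // 3)))
            for _ in range(n_steps):
                _stamp_disk(grid, pos, radius)
                theta += rng.normal(0.0, tortuosity)
                pos += np.array([np.sin(theta), np.cos(theta)])
                if not (0 <= pos[0] < height and 0 <= pos[1] < width):
                    break
                radius = max(r_min, radius * float(rng.uniform(0.985, 1.0)))
                if depth < 3 and radius > 1.5 * r_min and rng.random() < branch_prob:
                    n_children = int(rng.integers(1, 3))
                    for k in range(n_children):
                        dth = rng.uniform(0.4, 0.9) * (1 if k % 2 == 0 else -1)
                        child_r = max(r_min, radius * float(rng.uniform(0.6, 0.85)))
                        stack.append((pos.copy(), theta + dth, child_r, depth + 1))
    return VesselMask(grid=grid, pixel_size=pixel_size)


def _stamp_disk(grid: np.ndarray, pos: np.ndarray, radius: float) -> None:
    rr, cc = _skdraw.disk((pos[0], pos[1]), radius + 0.5, shape=grid.shape)
    grid[rr, cc] = True


# ---------------------------------------------------------------------------
# serialization: GraphML + JSON sidecar
# ---------------------------------------------------------------------------


def save_graph(g: VesselGraph, graphml_path: str, sidecar_path: str) -> None:
    """Write topology as GraphML and paths/radii/v_ref as a JSON sidecar."""
    topo = nx.MultiDiGraph() if g.directed else nx.MultiGraph()
    for eid, e in enumerate(g.edges):
        topo.add_edge(str(e.u), str(e.v), eid=eid)
    for v in g.vertices:
        topo.add_node(str(v))
    nx.write_graphml(topo, graphml_path)
    sidecar = {
        "shape": list(g.shape),
        "directed": g.directed,
        "edges": [
            {
                "u": list(e.u),
                "v": list(e.v),
                "path": e.path.tolist(),
                "radii": e.radii.tolist(),
                "v_ref": e.v_ref,
            }
            for e in g.edges
        ],
        "vertices": [list(v) for v in g.vertices],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, default=int)  # vertex coords may be numpy ints


def load_graph(sidecar_path: str) -> VesselGraph:
    """Rebuild a VesselGraph from its JSON sidecar (GraphML is derivable)."""
    with open(sidecar_path) as fh:
        data = json.load(fh)
    g = VesselGraph(shape=tuple(data["shape"]), directed=data["directed"])
    for ed in data["edges"]:
        g.add_edge(
            Edge(
                u=tuple(ed["u"]),
                v=tuple(ed["v"]),
                path=np.array(ed["path"], dtype=int),
                radii=np.array(ed["radii"], dtype=float),
                v_ref=float(ed["v_ref"]),
            )
        )
    for v in data["vertices"]:
        g.add_vertex(tuple(v))
    return g
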