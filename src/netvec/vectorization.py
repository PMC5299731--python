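"""Binary image -> weighted planar skeleton graph.

The vectorization pipeline follows the chordal-axis construction familiar
from optical character recognition:

1. the sub-pixel boundary of the (single) foreground component is traced
   and simplified into a polygon with holes (:func:`extract_contours`);
2. the polygon interior is triangulated with a constrained Delaunay
   triangulation whose vertices all lie on the boundary rings
   (:func:`triangulate`);
3. each triangle is classified by its number of internal (shared,
   non-boundary) edges -- END (1), SLEEVE (2), JUNCTION (3), ISOLATED (0)
   (:func:`classify_triangles`);
4. junction triangles become junction nodes, end triangles become tips,
   and chains of sleeve triangles become edges whose trajectories thread
   the midpoints of the shared edges (:func:`build_skeleton`).  Local
   half-widths (radii) are sampled from the Euclidean distance map.

The skeleton produced by :func:`build_skeleton` is *full*: every chordal
waypoint is materialized as a degree-2 "redundant" node carrying the
geometry of curved branches.  Pruning and redundancy reduction live in
:mod:`netvec.graph_ops`.

Graph convention
----------------
Skeleton graphs are :class:`networkx.MultiGraph` instances with node
attributes ``x, y, radius, kind`` (kind in ``{"tip", "junction",
"redundant"}``) and edge attributes ``trajectory`` (list of ``(x, y)``
tuples), ``length``, ``radius`` and ``n_triangles``.  Coordinates are
0-based pixel indices, origin at the top-left corner, ``x`` = column,
``y`` = row; positions may be sub-pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.polygon import orient
from skimage import measure

# Triangle classes, indexed by number of internal edges.
ISOLATED, END, SLEEVE, JUNCTION = 0, 1, 2, 3
CLASS_NAMES = {ISOLATED: "isolated", END: "end", SLEEVE: "sleeve", JUNCTION: "junction"}

DEFAULT_TOLERANCE = 1.0  # px, Douglas-Peucker contour simplification
DEFAULT_MAX_SEGMENT = 10.0  # px, boundary densification cap


class VectorizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distance map


def distance_map(binary: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance transform of the foreground (px units).

    Zero on background; on the skeleton its value is the local half-width
    of the shape, which is how edge radii are measured.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0:
        raise VectorizationError("empty image")
    return ndimage.distance_transform_edt(binary)


def sample_distance(dmap: np.ndarray, x: float, y: float) -> float:
    """Bilinear sample of the distance map at sub-pixel position (x, y)."""
    h, w = dmap.shape
    yy = min(max(float(y), 0.0), h - 1.0)
    xx = min(max(float(x), 0.0), w - 1.0)
    return float(ndimage.map_coordinates(dmap, [[yy], [xx]], order=1)[0])


# ---------------------------------------------------------------------------
# contours


@dataclass
class ShapePolygon:
    """Boundary of one connected foreground component.

    ``outer`` is counter-clockwise, ``holes`` are clockwise (image
    coordinates, y down); rings are open (no repeated closing vertex).
    """

    outer: np.ndarray  # (n, 2) float, columns (x, y)
    holes: list[np.ndarray] = field(default_factory=list)
    simplification_tolerance: float = DEFAULT_TOLERANCE


def _densify_ring(ring: np.ndarray, max_segment: float) -> np.ndarray:
    """Subdivide ring segments longer than ``max_segment`` into equal parts."""
    if max_segment <= 0 or len(ring) < 2:
        return ring
    out: list[np.ndarray] = []
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        out.append(a)
        dist = float(np.hypot(*(b - a)))
        k = int(math.ceil(dist / max_segment))
        for j in range(1, k):
            out.append(a + (b - a) * (j / k))
    return np.asarray(out)


def _ring_array(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    return arr


def extract_contours(
    binary: np.ndarray,
    tolerance: float = DEFAULT_TOLERANCE,
    max_segment: float = DEFAULT_MAX_SEGMENT,
) -> ShapePolygon:
    """Trace the sub-pixel boundary polygon of the foreground component.

    The marching-squares contour (level 0.5) of the mask is simplified by
    Douglas-Peucker at ``tolerance`` and then densified so that no boundary
    segment exceeds ``max_segment`` px.  Densification adds vertices *on*
    the rings only; it keeps the subsequent triangulation fine enough that
    sleeve-triangle chains sample the shape's width everywhere instead of
    spanning whole branches with a handful of skinny triangles.

    The input must contain exactly one 8-connected foreground component
    (apply :func:`netvec.segmentation.largest_component` first).
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise VectorizationError("extract_contours: no foreground")
    padded = np.pad(binary, 1).astype(float)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    rings = []
    for c in contours:
        # (row, col) -> (x, y), undo padding offset
        xy = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0])
        xy = _ring_array(xy)
        if len(xy) >= 3:
            rings.append(xy)
    if not rings:
        raise VectorizationError("degenerate component: no closed contour")

    polys = [Polygon(r) for r in rings]
    areas = [abs(p.area) for p in polys]
    outer_idx = int(np.argmax(areas))
    outer_ring = rings[outer_idx]
    hole_rings = [r for i, r in enumerate(rings) if i != outer_idx and areas[i] > 0]

    poly = Polygon(outer_ring, hole_rings)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    poly = poly.simplify(tolerance, preserve_topology=True)
    if isinstance(poly, MultiPolygon):
        poly = max(poly.geoms, key=lambda g: g.area)
    if poly.is_empty or poly.area <= 0 or not isinstance(poly, Polygon):
        raise VectorizationError("degenerate polygon after simplification")
    poly = orient(poly, sign=1.0)  # exterior CCW, holes CW

    outer = _densify_ring(_ring_array(poly.exterior.coords), max_segment)
    holes = [
        _densify_ring(_ring_array(h.coords), max_segment)
        for h in poly.interiors
        if len(h.coords) >= 4
    ]
    return ShapePolygon(outer=outer, holes=holes, simplification_tolerance=tolerance)


# ---------------------------------------------------------------------------
# triangulation


@dataclass
class Triangulation:
    """Constrained Delaunay triangulation of a shape's interior.

    ``triangles`` index into ``points``; ``boundary_edges`` holds the
    constrained ring edges as sorted index pairs; ``classes[i]`` is the
    triangle class (number of internal edges).
    """

    points: np.ndarray  # (n, 2) float
    triangles: np.ndarray  # (t, 3) int
    boundary_edges: set[tuple[int, int]]
    classes: np.ndarray | None = None  # (t,) int, filled by classify_triangles


def triangulate(shape: ShapePolygon) -> Triangulation:
    """Constrained Delaunay triangulation of the polygon interior.

    All ring edges appear as (constrained) triangulation edges and no
    Steiner points are inserted: every triangulation vertex is a polygon
    ring vertex.
    """
    poly = Polygon(shape.outer, shape.holes)
    if not poly.is_valid:
        raise VectorizationError(f"invalid polygon: {shapely.is_valid_reason(poly)}")
    cdt = shapely.constrained_delaunay_triangles(poly)
    if cdt.is_empty:
        raise VectorizationError("triangulation is empty")

    rings = [shape.outer] + list(shape.holes)
    points = np.concatenate(rings, axis=0)
    index: dict[tuple[float, float], int] = {}
    for i, (x, y) in enumerate(points):
        index.setdefault((round(float(x), 9), round(float(y), 9)), i)

    def vid(x: float, y: float) -> int:
        key = (round(float(x), 9), round(float(y), 9))
        try:
            return index[key]
        except KeyError:  # pragma: no cover - GEOS preserves input vertices
            raise VectorizationError("triangulation vertex not on polygon rings")

    triangles = []
    for geom in cdt.geoms:
        coords = list(geom.exterior.coords)[:3]
        triangles.append([vid(x, y) for x, y in coords])
    triangles = np.asarray(triangles, dtype=int)

    boundary: set[tuple[int, int]] = set()
    offset = 0
    for ring in rings:
        n = len(ring)
        for i in range(n):
            a, b = offset + i, offset + (i + 1) % n
            boundary.add((min(a, b), max(a, b)))
        offset += n
    return classify_triangles(
        Triangulation(points=points, triangles=triangles, boundary_edges=boundary)
    )


def _triangle_edges(tri: np.ndarray) -> list[tuple[int, int]]:
    a, b, c = (int(v) for v in tri)
    return [
        (min(a, b), max(a, b)),
        (min(b, c), max(b, c)),
        (min(a, c), max(a, c)),
    ]


def _edge_to_triangles(tri: Triangulation) -> dict[tuple[int, int], list[int]]:
    mapping: dict[tuple[int, int], list[int]] = {}
    for t, triple in enumerate(tri.triangles):
        for e in _triangle_edges(triple):
            mapping.setdefault(e, []).append(t)
    return mapping

def internal_edges(tri: Triangulation) -> dict[tuple[int, int], tuple[int, int]]:
    """Map each internal (shared, unconstrained) edge to its two triangles."""
    return {
        e: (ts[0], ts[1])
        for e, ts in _edge_to_triangles(tri).items()
        if len(ts) == 2 and e not in tri.boundary_edges
    }


def classify_triangles(tri: Triangulation) -> Triangulation:
    """Label triangles by their number of internal edges (0..3)."""
    shared = internal_edges(tri)
    classes = np.zeros(len(tri.triangles), dtype=int)
    for e, (t1, t2) in shared.items():
        classes[t1] += 1
        classes[t2] += 1
    tri.classes = classes
    return tri


# ---------------------------------------------------------------------------
# skeleton construction


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _centroid(tri: Triangulation, t: int) -> np.ndarray:
    return tri.points[tri.triangles[t]].mean(axis=0)


def build_skeleton(tri: Triangulation, dmap: np.ndarray) -> nx.MultiGraph:
    """Chordal-axis skeleton of a classified triangulation.

    Junction triangles contribute junction nodes at their centroids
    (adjacent junction triangles merge into one node at the joint
    centroid); end triangles contribute tip nodes at the boundary vertex
    opposite their single internal edge; sleeve chains contribute paths
    threading the midpoints of shared edges.  Every waypoint becomes a
    degree-2 redundant node so that the full geometry is retained; each
    elementary edge stores its 2-point trajectory, length, mean radius and
    the number of sleeve triangles it crosses.

    Pure sleeve cycles (rings without any junction or end triangle) are
    anchored at the triangle whose centroid has the smallest (y, x), so the
    loop survives as a closed chain through that anchor.
    """
    if tri.classes is None:
        tri = classify_triangles(tri)
    n_tri = len(tri.triangles)
    if n_tri == 0:
        raise VectorizationError("empty triangulation")
    shared = internal_edges(tri)
    tri_internal: dict[int, list[tuple[int, int]]] = {t: [] for t in range(n_tri)}
    for e, (t1, t2) in shared.items():
        tri_internal[t1].append(e)
        tri_internal[t2].append(e)
    for t in tri_internal:
        tri_internal[t].sort()

    def across(e: tuple[int, int], t: int) -> int:
        t1, t2 = shared[e]
        return t2 if t1 == t else t1

    classes = tri.classes
    uf = _UnionFind(n_tri)
    for e, (t1, t2) in shared.items():
        if classes[t1] == JUNCTION and classes[t2] == JUNCTION:
            uf.union(t1, t2)

    # entity = skeleton node seed: end triangle, junction cluster, isolated
    # triangle, or cycle anchor.  Keyed by representative triangle index.
    entity_of: dict[int, int] = {}  # triangle -> entity id
    entity_pos: list[np.ndarray] = []
    entity_kind: list[str] = []

    clusters: dict[int, list[int]] = {}
    for t in range(n_tri):
        if classes[t] == JUNCTION:
            clusters.setdefault(uf.find(t), []).append(t)

    for t in range(n_tri):
        if classes[t] == END:
            e = tri_internal[t][0]
            opposite = [v for v in tri.triangles[t] if v not in e]
            entity_of[t] = len(entity_pos)
            entity_pos.append(tri.points[opposite[0]].astype(float))
            entity_kind.append("tip")
        elif classes[t] == ISOLATED:
            entity_of[t] = len(entity_pos)
            entity_pos.append(_centroid(tri, t))
            entity_kind.append("tip")
        elif classes[t] == JUNCTION and uf.find(t) == t:
            members = clusters[t]
            eid = len(entity_pos)
            entity_pos.append(np.mean([_centroid(tri, m) for m in members], axis=0))
            entity_kind.append("junction")
            for m in members:
                entity_of[m] = eid

    # anchors for pure sleeve cycles: components with no entity triangle
    seen = np.zeros(n_tri, dtype=bool)
    for t in range(n_tri):
        if seen[t] or classes[t] != SLEEVE:
            continue
        stack, comp, has_entity = [t], [], False
        seen[t] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for e in tri_internal[cur]:
                nb = across(e, cur)
                if classes[nb] != SLEEVE:
                    has_entity = True
                elif not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        if not has_entity:
            anchor = min(comp, key=lambda m: (tuple(_centroid(tri, m)[::-1])))
            entity_of[anchor] = len(entity_pos)
            entity_pos.append(_centroid(tri, anchor))
            entity_kind.append("redundant")

    # walk sleeve chains between entities
    g = nx.MultiGraph()
    g.graph["image_shape"] = tuple(int(s) for s in dmap.shape)

    def node_radius(pos: np.ndarray) -> float:
        return sample_distance(dmap, pos[0], pos[1])

    for eid, (pos, kind) in enumerate(zip(entity_pos, entity_kind)):
        g.add_node(
            eid, x=float(pos[0]), y=float(pos[1]), radius=node_radius(pos), kind=kind
        )
    next_id = len(entity_pos)

    def midpoint(e: tuple[int, int]) -> np.ndarray:
        return tri.points[list(e)].mean(axis=0)

    visited_starts: set[tuple[int, tuple[int, int]]] = set()
    member_tris = sorted(entity_of)
    for t0 in member_tris:
        for e0 in tri_internal[t0]:
            nb0 = across(e0, t0)
            if entity_of.get(nb0) == entity_of[t0] and classes[t0] == JUNCTION:
                continue  # edge interior to a merged junction cluster
            if (t0, e0) in visited_starts:
                continue
            visited_starts.add((t0, e0))
            waypoints = [midpoint(e0)]
            sleeves = 0
            prev_edge, cur = e0, nb0
            while cur not in entity_of:
                nxt = [e for e in tri_internal[cur] if e != prev_edge][0]
                waypoints.append(midpoint(nxt))
                sleeves += 1
                prev_edge, cur = nxt, across(nxt, cur)
            visited_starts.add((cur, prev_edge))
            start_ent, end_ent = entity_of[t0], entity_of[cur]
            is_cycle_chain = (
                start_ent == end_ent and entity_kind[start_ent] == "redundant"
            )

            path = [np.asarray(entity_pos[start_ent])] + waypoints + [
                np.asarray(entity_pos[end_ent])
            ]
            node_ids = [start_ent]
            for w in waypoints:
                g.add_node(
                    next_id,
                    x=float(w[0]),
                    y=float(w[1]),
                    radius=node_radius(w),
                    kind="redundant",
                )
                node_ids.append(next_id)
                next_id += 1
            node_ids.append(end_ent)

            n_seg = len(path) - 1
            for i in range(n_seg):
                u, v = node_ids[i], node_ids[i + 1]
                p, q = path[i], path[i + 1]
                seg_tris = 1 if 0 < i < n_seg - 1 else 0
                if is_cycle_chain and i == n_seg - 1:
                    seg_tris += 1  # count the anchor triangle itself
                g.add_edge(
                    u,
                    v,
                    trajectory=[(float(p[0]), float(p[1])), (float(q[0]), float(q[1]))],
                    length=float(np.hypot(*(q - p))),
                    radius=(g.nodes[u]["radius"] + g.nodes[v]["radius"]) / 2.0,
                    n_triangles=seg_tris,
                )
    return g


# ---------------------------------------------------------------------------
# high-level pipeline


def extract_network(
    binary: np.ndarray,
    p: int = 0,
    r: int = 2,
    tolerance: float = DEFAULT_TOLERANCE,
    max_segment: float = DEFAULT_MAX_SEGMENT,
    dmap: np.ndarray | None = None,
) -> nx.MultiGraph:
    """Full extraction: contours -> triangulation -> skeleton -> prune(p) ->
    redundancy level ``r``.

    ``p`` is the pruning threshold in triangles (0 = no pruning); ``r`` in
    {0, 1, 2} keeps none, half or all redundant (degree-2) nodes.
    """
    from netvec import graph_ops  # deferred: graph_ops imports sample_distance

    if dmap is None:
        dmap = distance_map(binary)
    shape = extract_contours(binary, tolerance=tolerance, max_segment=max_segment)
    tri = triangulate(shape)
    g = build_skeleton(tri, dmap)
    g.graph["params"] = {
        "p": int(p),
        "r": int(r),
        "tolerance": float(tolerance),
        "max_segment": float(max_segment),
    }
    g = graph_ops.prune(g, p)
    g = graph_ops.reduce_redundancy(g, r)
    return g
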