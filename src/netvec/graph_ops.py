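"""Skeleton-graph post-processing and editing primitives.

Operates on the ``networkx.MultiGraph`` skeleton convention described in
:mod:`netvec.vectorization`:

* :func:`prune` removes short dangling branches (surplus twigs caused by
  contour kinks), measured in triangles;
* :func:`reduce_redundancy` controls how many geometry-carrying degree-2
  ("redundant") nodes are kept (r = 0 none, 1 half, 2 all);
* node/edge editing primitives mirror the interactive corrections needed
  for non-planar networks whose projections contain spurious junctions.

All operations are functional: they return a modified copy and leave the
input graph untouched.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from netvec.vectorization import sample_distance


class GraphOpError(ValueError):
    pass


# ---------------------------------------------------------------------------
# helpers

def node_pos(g: nx.MultiGraph, n) -> tuple[float, float]:
    d = g.nodes[n]
    return (d["x"], d["y"])


def total_length(g: nx.MultiGraph) -> float:
    return float(sum(d["length"] for _, _, d in g.edges(data=True)))


def update_kinds(g: nx.MultiGraph) -> nx.MultiGraph:
    """Refresh node kinds from degrees: 1 -> tip, 2 -> redundant, >=3 -> junction."""
    for n in g.nodes:
        deg = g.degree(n)
        if deg >= 3:
            g.nodes[n]["kind"] = "junction"
        elif deg == 2:
            g.nodes[n]["kind"] = "redundant"
        else:
            g.nodes[n]["kind"] = "tip"
    return g


def _oriented_trajectory(g: nx.MultiGraph, a, data: dict) -> list[tuple[float, float]]:
    """Edge trajectory oriented to start at node ``a``."""
    traj = data["trajectory"]
    pa = np.asarray(node_pos(g, a))
    d0 = float(np.hypot(*(np.asarray(traj[0]) - pa)))
    d1 = float(np.hypot(*(np.asarray(traj[-1]) - pa)))
    return list(traj) if d0 <= d1 else list(traj)[::-1]


def _merged_edge_data(
    g: nx.MultiGraph, path_nodes: Sequence, path_edges: Sequence[tuple]
) -> dict:
    """Concatenate a chain of edges into one edge record.

    ``path_nodes`` lists the nodes visited (terminals included),
    ``path_edges`` the (u, v, key) of each traversed edge in order.
    Lengths and triangle counts are summed and the radius is the
    length-weighted mean, so that total network length and the mean-radius
    semantics are conserved exactly.
    """
    traj: list[tuple[float, float]] = []
    length = 0.0
    n_tri = 0
    weighted_r = 0.0
    plain_r = []
    for start, (u, v, k) in zip(path_nodes, path_edges):
        d = g.edges[u, v, k]
        part = _oriented_trajectory(g, start, d)
        if traj:
            part = part[1:]
        traj.extend(part)
        length += d["length"]
        n_tri += d["n_triangles"]
        weighted_r += d["radius"] * d["length"]
        plain_r.append(d["radius"])
    radius = weighted_r / length if length > 0 else float(np.mean(plain_r))
    return {
        "trajectory": traj,
        "length": length,
        "radius": radius,
        "n_triangles": n_tri,
    }


def _merge_through(g: nx.MultiGraph, n) -> None:
    """Replace a degree-2 node by a single through-edge (in place)."""
    inc = sorted(g.edges(n, keys=True), key=lambda e: (e[1], e[2]))
    if len(inc) != 2:
        raise GraphOpError(f"cannot merge through node {n}: degree != 2")
    (_, a, k1), (_, b, k2) = inc
    d1 = g.edges[n, a, k1]
    d2 = g.edges[n, b, k2]
    data = _merged_edge_data(g, [a, n], [(a, n, k1), (n, b, k2)])
    g.remove_node(n)
    g.add_edge(a, b, **data)


def _pure_cycle_anchors(g: nx.MultiGraph) -> set:
    """One designated survivor per connected component that is a pure cycle
    of degree-2 nodes (the case of a ring with no junctions); chosen as the
    node with the smallest (y, x) position."""
    anchors = set()
    for comp in nx.connected_components(g):
        if all(g.degree(n) == 2 for n in comp) and not any(
            g.has_edge(n, n) for n in comp
        ):
            anchors.add(
                min(comp, key=lambda n: (g.nodes[n]["y"], g.nodes[n]["x"], n))
            )
    return anchors


def _chains(g: nx.MultiGraph):
    """Maximal paths of degree-2 nodes between terminal (degree != 2 or
    self-looped) nodes, plus pure cycles.

    Yields tuples ``(nodes, edges)`` where nodes = [t0, i1, ..., im, t1]
    and edges the corresponding (u, v, key) list.  For pure cycles the
    anchor plays both terminal roles.
    """
    def is_terminal(n):
        return g.degree(n) != 2 or g.has_edge(n, n)

    visited: set[tuple] = set()

    def canon(u, v, k):
        return (u, v, k) if u <= v else (v, u, k)

    chains = []
    for t in sorted(g.nodes):
        if not is_terminal(t):
            continue
        for _, nbr, k in sorted(g.edges(t, keys=True), key=lambda e: (e[1], e[2])):
            if nbr == t or canon(t, nbr, k) in visited:
                continue
            nodes, edges = [t], []
            cur, prev = nbr, (t, nbr, k)
            visited.add(canon(*prev))
            edges.append(prev)
            while not is_terminal(cur):
                nodes.append(cur)
                nxt = [
                    (cur, m, kk)
                    for _, m, kk in sorted(
                        g.edges(cur, keys=True), key=lambda e: (e[1], e[2])
                    )
                    if canon(cur, m, kk) != canon(*prev)
                ][0]
                visited.add(canon(*nxt))
                edges.append(nxt)
                prev, cur = nxt, nxt[1]
            nodes.append(cur)
            chains.append((nodes, edges))
    # pure cycles: all nodes degree 2, never reached from a terminal
    for anchor in sorted(_pure_cycle_anchors(g)):
        nodes, edges = [anchor], []
        first = sorted(g.edges(anchor, keys=True), key=lambda e: (e[1], e[2]))[0]
        cur, prev = first[1], (anchor, first[1], first[2])
        edges.append(prev)
        while cur != anchor:
            nodes.append(cur)
            nxt = [
                (cur, m, kk)
                for _, m, kk in sorted(
                    g.edges(cur, keys=True), key=lambda e: (e[1], e[2])
                )
                if canon(cur, m, kk) != canon(*prev)
            ][0]
            edges.append(nxt)
            prev, cur = nxt, nxt[1]
        nodes.append(anchor)
        chains.append((nodes, edges))
    return chains


# ---------------------------------------------------------------------------
# pruning


def prune(g: nx.MultiGraph, p: int) -> nx.MultiGraph:
    """Remove dangling branches shorter than ``p`` triangles.

    A dangling branch is the path from a tip (degree-1 node) to the
    nearest junction (degree >= 3); it is removed when the sum of its
    edges' ``n_triangles`` is strictly less than ``p``.  Removal iterates
    to a fixed point, since deleting one branch can expose another short
    one.  Junctions whose degree drops to 2 are then merged into a single
    through-edge.  Whole-path components (no junction) and edges between
    two junctions are never removed; ``p = 0`` is the identity.
    """
    if p < 0:
        raise GraphOpError(f"pruning threshold must be >= 0, got {p}")
    g = g.copy()
    if p == 0:
        return g

    changed = True
    while changed:
        changed = False
        # decide all removals on the sweep-start graph, then apply at once:
        # this keeps the outcome independent of tip iteration order
        branches: list[tuple[int, object, list]] = []  # (n_tri, junction, nodes)
        for tip in sorted(n for n in g.nodes if g.degree(n) == 1):
            branch_nodes = [tip]
            n_tri = 0
            cur = tip
            prev_edge = None
            junction = None
            while True:
                inc = [
                    (u, v, k)
                    for u, v, k in sorted(
                        g.edges(cur, keys=True), key=lambda e: (e[1], e[2])
                    )
                    if prev_edge is None
                    or (min(u, v), max(u, v), k)
                    != (min(prev_edge[:2]), max(prev_edge[:2]), prev_edge[2])
                ]
                if not inc:
                    break  # isolated path end
                _, nxt, k = inc[0]
                n_tri += g.edges[cur, nxt, k]["n_triangles"]
                if g.degree(nxt) >= 3 or g.has_edge(nxt, nxt):
                    junction = nxt
                    break
                if g.degree(nxt) != 2 or nxt in branch_nodes:
                    break  # other tip (pure path) or loop: keep
                branch_nodes.append(nxt)
                prev_edge = (cur, nxt, k)
                cur = nxt
            if junction is not None and n_tri < p:
                branches.append((n_tri, junction, branch_nodes))
        # a junction must not lose every incident edge: when all of its
        # branches are short, the longest one is spared (so a bare tree
        # keeps its longest chain instead of vanishing)
        per_junction: dict = {}
        for idx, (_, junction, _nodes) in enumerate(branches):
            per_junction.setdefault(junction, []).append(idx)
        spared: set[int] = set()
        for junction, idxs in per_junction.items():
            if len(idxs) == g.degree(junction):
                keep = max(
                    idxs, key=lambda i: (branches[i][0], len(branches[i][2]), -i)
                )
                spared.add(keep)
        doomed: set = set()
        for idx, (_, _junction, nodes) in enumerate(branches):
            if idx not in spared:
                doomed.update(nodes)
        if doomed:
            g.remove_nodes_from(doomed)
            changed = True
        # collapse junctions that lost all but two incident branches before
        # re-walking, so surviving arms accumulate their full triangle count
        for n in sorted(g.nodes):
            if (
                g.nodes[n].get("kind") == "junction"
                and g.degree(n) == 2
                and not g.has_edge(n, n)
            ):
                _merge_through(g, n)
    return update_kinds(g)


# ---------------------------------------------------------------------------
# redundancy reduction


def reduce_redundancy(g: nx.MultiGraph, r: int) -> nx.MultiGraph:
    """Keep none (r=0), half (r=1) or all (r=2) redundant degree-2 nodes.

    Total network length, triangle counts and the length-weighted mean
    radius of each merged chain are conserved exactly.  For r=1 every
    second interior node is removed counting from the lower-id terminal, so
    the interior count is halved (rounded up).  Pure cycles keep a
    deterministic anchor node (smallest (y, x)) so the loop survives.
    """
    if r not in (0, 1, 2):
        raise GraphOpError(f"redundancy level must be 0, 1 or 2, got {r}")
    g = g.copy()
    if r == 2:
        return g
    anchors = _pure_cycle_anchors(g)
    for nodes, _edges in _chains(g):
        t0, t1 = nodes[0], nodes[-1]
        interior = nodes[1:-1]
        if not interior:
            continue
        if t0 == t1:  # loop (pure cycle through its anchor, or lasso at a junction)
            if interior[0] > interior[-1]:
                interior = interior[::-1]
        elif t0 > t1:
            interior = interior[::-1]
        doomed = interior if r == 0 else interior[1::2]
        for n in doomed:
            if n in anchors:
                continue
            _merge_through(g, n)
    return update_kinds(g)


# ---------------------------------------------------------------------------
# cycles


def find_cycles(g: nx.MultiGraph) -> list[list]:
    """A cycle basis of the skeleton graph (empty iff the graph is a forest).

    Loops still present in an extracted tracheole network usually mark
    spurious junctions from branch crossings in the 2-D projection;
    highlighting them is the first step of manual correction.  Handles
    parallel edges and self-loops, which plain cycle-basis routines do not.
    """
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    cycles: list[list] = []
    dummy = 0
    for u, v, k in g.edges(keys=True):
        if u == v:
            cycles.append([u])
        elif h.has_edge(u, v):
            # subdivide parallel edges so the simple-graph basis sees them
            name = ("__dummy__", dummy)
            dummy += 1
            h.add_edge(u, name)
            h.add_edge(name, v)
        else:
            h.add_edge(u, v)
    for cyc in nx.cycle_basis(h):
        cycles.append([n for n in cyc if not (isinstance(n, tuple) and n and n[0] == "__dummy__")])
    return cycles


# ---------------------------------------------------------------------------
# editing primitives


def remove_node(g: nx.MultiGraph, node) -> nx.MultiGraph:
    """Delete a node and all incident edges."""
    if node not in g:
        raise GraphOpError(f"no node with id {node!r}")
    g = g.copy()
    g.remove_node(node)
    return update_kinds(g)


def add_node(g: nx.MultiGraph, x: float, y: float, dmap: np.ndarray):
    """Add a node at (x, y); its radius is measured from the distance map.

    Returns ``(graph, node_id)``; the fresh id is one past the largest
    existing id.
    """
    h, w = dmap.shape
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise GraphOpError(f"position ({x}, {y}) outside image bounds {w}x{h}")
    g = g.copy()
    new_id = max((n for n in g.nodes if isinstance(n, int)), default=-1) + 1
    g.add_node(
        new_id,
        x=float(x),
        y=float(y),
        radius=sample_distance(dmap, x, y),
        kind="tip",
    )
    return g, new_id


def add_edge(g: nx.MultiGraph, u, v) -> nx.MultiGraph:
    """Connect two existing nodes with a straight edge.

    The trajectory is the straight segment between the node positions, the
    radius the mean of the two node radii; ``n_triangles`` is 0 since the
    edge does not stem from the triangulation.
    """
    if u not in g or v not in g:
        raise GraphOpError(f"add_edge: unknown node in ({u!r}, {v!r})")
    if g.has_edge(u, v):
        raise GraphOpError(f"edge ({u!r}, {v!r}) already exists")
    g = g.copy()
    pu, pv = np.asarray(node_pos(g, u)), np.asarray(node_pos(g, v))
    g.add_edge(
        u,
        v,
        trajectory=[tuple(map(float, pu)), tuple(map(float, pv))],
        length=float(np.hypot(*(pv - pu))),
        radius=(g.nodes[u]["radius"] + g.nodes[v]["radius"]) / 2.0,
        n_triangles=0,
    )
    return update_kinds(g)


def remove_edge(g: nx.MultiGraph, u, v) -> nx.MultiGraph:
    """Remove one (u, v) edge; the nodes stay."""
    if not g.has_edge(u, v):
        raise GraphOpError(f"no edge between {u!r} and {v!r}")
    g = g.copy()
    g.remove_edge(u, v)
    return update_kinds(g)


def keep_largest_graph_component(g: nx.MultiGraph) -> nx.MultiGraph:
    """Keep the connected component with the greatest total edge length.

    Ties are broken by node count, then by smallest node id.
    """
    if g.number_of_nodes() == 0:
        raise GraphOpError("empty graph")
    comps = list(nx.connected_components(g))
    def score(comp):
        sub = g.subgraph(comp)
        return (total_length(sub), len(comp), -min(comp))
    best = max(comps, key=score)
    return g.subgraph(best).copy()


def apply_edits(
    g: nx.MultiGraph, script: Iterable[dict], dmap: np.ndarray | None = None
) -> nx.MultiGraph:
    """Apply a batch edit script: a list of ``{"op": ..., ...args}`` dicts.

    Supported ops: ``remove_node`` (id), ``add_node`` (x, y; needs a
    distance map), ``add_edge`` (u, v), ``remove_edge`` (u, v).  This is the
    headless counterpart of interactive point-and-click graph correction.
    """
    for step in script:
        op = step.get("op")
        if op == "remove_node":
            g = remove_node(g, step["id"])
        elif op == "add_node":
            if dmap is None:
                raise GraphOpError("add_node requires a distance map")
            g, _ = add_node(g, step["x"], step["y"], dmap)
        elif op == "add_edge":
            g = add_edge(g, step["u"], step["v"])
        elif op == "remove_edge":
            g = remove_edge(g, step["u"], step["v"])
        else:
            raise GraphOpError(f"unknown edit operation {op!r}")
    return g
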