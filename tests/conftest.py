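"""Shared fixtures: rasterized shape masks and hand-built skeleton graphs."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from netvec import graph_ops
from netvec.validation import _stroke


def stroke_mask(shape, segments, radius):
    """Binary mask with the given (p, q) segments stroked at ``radius``."""
    canvas = np.zeros(shape)
    for p, q in segments:
        _stroke(canvas, p, q, radius, 1.0)
    return canvas > 0


@pytest.fixture(scope="session")
def bar_mask():
    """100 x 10 px horizontal bar."""
    img = np.zeros((30, 120), dtype=bool)
    img[10:20, 10:110] = True
    return img


@pytest.fixture(scope="session")
def y_mask():
    """Three 50-px arms of half-width 5 meeting at the center."""
    c = np.array([70.0, 70.0])
    segs = []
    for ang in (80, 200, 320):
        a = math.radians(ang)
        segs.append((c, c + 50 * np.array([math.cos(a), math.sin(a)])))
    return stroke_mask((140, 140), segs, 5.0)


@pytest.fixture(scope="session")
def annulus_mask():
    yy, xx = np.mgrid[0:100, 0:100]
    rr = np.hypot(yy - 50, xx - 50)
    return (rr > 25) & (rr < 35)


@pytest.fixture(scope="session")
def disk_mask():
    yy, xx = np.mgrid[0:40, 0:40]
    return np.hypot(yy - 20, xx - 20) <= 10


def add_chain(g, start_id, positions, n_triangles=1, radius=1.0):
    """Append a chain of unit elementary edges to ``g``; returns node ids."""
    ids = []
    for i, (x, y) in enumerate(positions):
        nid = start_id + i
        if nid not in g:
            g.add_node(nid, x=float(x), y=float(y), radius=radius, kind="redundant")
        ids.append(nid)
    for a, b in zip(ids[:-1], ids[1:]):
        pa = (g.nodes[a]["x"], g.nodes[a]["y"])
        pb = (g.nodes[b]["x"], g.nodes[b]["y"])
        g.add_edge(
            a,
            b,
            trajectory=[pa, pb],
            length=float(np.hypot(pb[0] - pa[0], pb[1] - pa[1])),
            radius=radius,
            n_triangles=n_triangles,
        )
    return ids


def make_ring_graph(n=8, radius=20.0, center=(50.0, 50.0)):
    """Closed ring of ``n`` degree-2 nodes (a pure cycle)."""
    g = nx.MultiGraph()
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pos = np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )
    ids = add_chain(g, 0, [tuple(p) for p in pos])
    a, b = ids[-1], ids[0]
    pa = (g.nodes[a]["x"], g.nodes[a]["y"])
    pb = (g.nodes[b]["x"], g.nodes[b]["y"])
    g.add_edge(a, b, trajectory=[pa, pb],
               length=float(np.hypot(pb[0] - pa[0], pb[1] - pa[1])),
               radius=1.0, n_triangles=1)
    return graph_ops.update_kinds(g)


def make_path_graph(n=5, spacing=10.0):
    """Straight path of ``n`` collinear nodes."""
    g = nx.MultiGraph()
    add_chain(g, 0, [(i * spacing, 0.0) for i in range(n)])
    return graph_ops.update_kinds(g)


def make_y_graph(arm_triangles=(10, 10, 2)):
    """Star with three arms; each arm edge carries 1 triangle per segment.

    Arm k extends from the hub (node 0 at origin) with ``arm_triangles[k]``
    elementary edges of length 10 each.
    """
    g = nx.MultiGraph()
    g.add_node(0, x=0.0, y=0.0, radius=1.0, kind="junction")
    directions = [(1.0, 0.0), (-0.5, 0.87), (-0.5, -0.87)]
    nid = 1
    for n_seg, (dx, dy) in zip(arm_triangles, directions):
        positions = [(0.0, 0.0)] + [
            (dx * 10 * (i + 1), dy * 10 * (i + 1)) for i in range(n_seg)
        ]
        g.add_node(nid, x=positions[1][0], y=positions[1][1], radius=1.0,
                   kind="redundant")
        prev = 0
        for i, pos in enumerate(positions[1:]):
            cur = nid + i
            if cur not in g:
                g.add_node(cur, x=pos[0], y=pos[1], radius=1.0, kind="redundant")
            pa = (g.nodes[prev]["x"], g.nodes[prev]["y"])
            g.add_edge(
                prev,
                cur,
                trajectory=[pa, pos],
                length=float(np.hypot(pos[0] - pa[0], pos[1] - pa[1])),
                radius=1.0,
                n_triangles=1,
            )
            prev = cur
        nid += n_seg
    return graph_ops.update_kinds(g)


def make_h_graph():
    """H-shape: two verticals joined by a crossbar; 4 tips, 2 junctions."""
    g = nx.MultiGraph()
    chains = [
        [(0, 0), (0, 10), (0, 20)],        # left top arm
        [(0, 20), (0, 30), (0, 40)],       # left bottom arm
        [(30, 0), (30, 10), (30, 20)],     # right top arm
        [(30, 20), (30, 30), (30, 40)],    # right bottom arm
        [(0, 20), (10, 20), (20, 20), (30, 20)],  # crossbar
    ]
    coords: dict[tuple, int] = {}
    nid = 0
    for chain in chains:
        ids = []
        for x, y in chain:
            if (x, y) not in coords:
                g.add_node(nid, x=float(x), y=float(y), radius=1.0, kind="redundant")
                coords[(x, y)] = nid
                nid += 1
            ids.append(coords[(x, y)])
        for a, b in zip(ids[:-1], ids[1:]):
            pa = (g.nodes[a]["x"], g.nodes[a]["y"])
            pb = (g.nodes[b]["x"], g.nodes[b]["y"])
            g.add_edge(a, b, trajectory=[pa, pb],
                       length=float(np.hypot(pb[0] - pa[0], pb[1] - pa[1])),
                       radius=1.0, n_triangles=1)
    return graph_ops.update_kinds(g)


def make_grid_graph(n=4, spacing=10.0):
    """n x n lattice with unit-triangle edges (rich in cycles)."""
    g = nx.MultiGraph()
    def nid(i, j):
        return i * n + j
    for i in range(n):
        for j in range(n):
            g.add_node(nid(i, j), x=j * spacing, y=i * spacing, radius=1.0,
                       kind="redundant")
    for i in range(n):
        for j in range(n):
            for di, dj in ((0, 1), (1, 0)):
                if i + di < n and j + dj < n:
                    a, b = nid(i, j), nid(i + di, j + dj)
                    pa = (g.nodes[a]["x"], g.nodes[a]["y"])
                    pb = (g.nodes[b]["x"], g.nodes[b]["y"])
                    g.add_edge(a, b, trajectory=[pa, pb], length=spacing,
                               radius=1.0, n_triangles=1)
    return graph_ops.update_kinds(g)


@pytest.fixture
def path_graph():
    return make_path_graph()


@pytest.fixture
def y_graph():
    return make_y_graph()


@pytest.fixture
def h_graph():
    return make_h_graph()


@pytest.fixture
def grid_graph():
    return make_grid_graph()
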