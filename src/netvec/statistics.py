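"""Scalar descriptors of an extracted network.

The descriptors cover the quantities used both for routine analysis and
for round-trip validation: node count N, total length L (sum of edge
lengths), length-weighted mean edge radius R-bar, the ratio
r = min(R)/max(R) of the extreme edge radii, the convex-hull area of the
node positions, and degree/cycle counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError

from netvec import graph_ops


@dataclass
class NetworkStats:
    n_nodes: int
    total_length: float
    mean_radius: float
    radius_ratio: float
    hull_area: float
    n_tips: int
    n_junctions: int
    n_cycles: int


def compute_stats(g: nx.MultiGraph) -> NetworkStats:
    """Compute the standard descriptors of a skeleton graph.

    The mean radius is weighted by edge length, so a long vein contributes
    to R-bar in proportion to its extent in the image; the radius ratio is
    taken over edge radii.  ``n_cycles`` is the cycle-space dimension
    E - V + C.  Raises on an empty graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute statistics of an empty graph")
    lengths = np.array([d["length"] for _, _, d in g.edges(data=True)], dtype=float)
    radii = np.array([d["radius"] for _, _, d in g.edges(data=True)], dtype=float)
    total = float(lengths.sum())
    if len(radii) == 0:
        mean_radius, ratio = 0.0, math.nan
    elif total > 0:
        mean_radius = float((radii * lengths).sum() / total)
        ratio = float(radii.min() / radii.max()) if radii.max() > 0 else math.nan
    else:
        mean_radius = float(radii.mean())
        ratio = float(radii.min() / radii.max()) if radii.max() > 0 else math.nan

    coords = np.array([[d["x"], d["y"]] for _, d in g.nodes(data=True)], dtype=float)
    try:
        hull_area = float(ConvexHull(coords).volume)  # 2-D "volume" is area
    except (QhullError, ValueError):
        hull_area = 0.0  # fewer than 3 nodes, or all collinear

    degrees = dict(g.degree())
    n_comp = nx.number_connected_components(g)
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        total_length=total,
        mean_radius=mean_radius,
        radius_ratio=ratio,
        hull_area=hull_area,
        n_tips=sum(1 for d in degrees.values() if d == 1),
        n_junctions=sum(1 for d in degrees.values() if d >= 3),
        n_cycles=g.number_of_edges() - g.number_of_nodes() + n_comp,
    )


def write_stats(stats: NetworkStats, path) -> None:
    """Write stats as a tab-separated key/value file (one line per field).

    Field order is fixed and floats use 6 significant digits, so two
    identical graphs produce byte-identical files.
    """
    lines = []
    for f in fields(stats):
        value = getattr(stats, f.name)
        if isinstance(value, int):
            lines.append(f"{f.name}\t{value}")
        else:
            lines.append(f"{f.name}\t{value:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_stats(path) -> NetworkStats:
    """Parse a file written by :func:`write_stats`."""
    values = {}
    for line in Path(path).read_text().splitlines():
        key, raw = line.split("\t")
        values[key] = raw
    kwargs = {}
    for f in fields(NetworkStats):
        kwargs[f.name] = (int if f.type == "int" else float)(values[f.name])
    return NetworkStats(**kwargs)


def cycle_count(g: nx.MultiGraph) -> int:
    """Independent cycle count via explicit basis enumeration."""
    return len(graph_ops.find_cycles(g))
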