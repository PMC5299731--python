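"""Round-trip validation on synthetic networks.

The extraction error of the whole pipeline is quantified by a round trip:
generate a known planar network, render it as a grayscale image on a
spatially correlated noise background with per-edge intensity variation
(emulating uneven illumination and staining in micrographs), segment and
re-extract it, and compare observables between the known and re-extracted
graphs.  For an observable S the relative extraction error is

    sigma_S = |S_o - S_v| / S_o

with S_o measured on the original network and S_v on the re-extracted
one.  The observables are the node count N, total length L, the
length-weighted mean edge radius R-bar and the radius ratio
r = min(R)/max(R).  A pixel-wise difference D between the rasterized
networks (no alignment applied) additionally checks that no spatial
transformation crept in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import distance_matrix
from shapely.geometry import LineString, Point

from netvec import graph_ops
from netvec.segmentation import SegmentationParams, binarize_adaptive, largest_component
from netvec.statistics import compute_stats
from netvec.vectorization import extract_network


# ---------------------------------------------------------------------------
# parameters


@dataclass
class SyntheticNetworkParams:
    """Generator settings for seeded random planar networks.

    Nodes are sampled with a minimum-separation constraint inside the
    extent (keeping a border margin so rendered strokes stay inside the
    image), connected by their Euclidean minimum spanning tree, and
    reticulated by the shortest non-crossing extra edges.  Radii taper
    monotonically with hop distance from a root node, like the vein
    hierarchy of a leaf.
    """

    n_points: int = 100
    extent: tuple[int, int] = (512, 512)  # (width, height) px
    radius_range: tuple[float, float] = (2.0, 6.0)
    loop_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.radius_range[0] < 1:
            raise ValueError("minimum radius must be >= 1 px")
        if not 0 <= self.loop_fraction <= 0.5:
            raise ValueError("loop_fraction must lie in [0, 0.5]")


@dataclass
class RenderParams:
    """Rasterization settings for synthetic network images."""

    edge_intensity_range: tuple[float, float] = (0.5, 1.0)
    noise_amplitude: float = 0.1
    noise_correlation_length: float = 5.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.edge_intensity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("edge intensities must satisfy 0 < low <= high <= 1")
        if self.noise_amplitude < 0 or self.noise_correlation_length < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class ExtractParams:
    """Pipeline settings used when re-extracting rendered networks."""

    p: int = 3
    r: int = 0
    tolerance: float = 0.5
    max_segment: float = 10.0
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(
            block_size=51,
            offset=0.14,
            min_hole_area=30.0,
            opening_radius=0,
            closing_radius=1,
        )
    )


# ---------------------------------------------------------------------------
# synthetic networks


def _sample_points(rng, n: int, extent, margin: float) -> np.ndarray:
    """Blue-noise-ish sampling: uniform draws with a minimum separation."""
    w, h = extent
    area = max((w - 2 * margin), 1) * max((h - 2 * margin), 1)
    min_dist = 0.45 * math.sqrt(area / n)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n and attempts < 500 * n:
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        attempts += 1
        if all(np.hypot(*(cand - p)) >= min_dist for p in pts):
            pts.append(cand)
    while len(pts) < n:  # degenerate extents: fall back to unconstrained
        pts.append(rng.uniform([margin, margin], [w - margin, h - margin]))
    return np.asarray(pts)


def _segments_cross(ls: LineString, other: LineString, shared: bool) -> bool:
    inter = ls.intersection(other)
    if inter.is_empty:
        return False
    if shared and isinstance(inter, Point):
        return False  # touching at the shared endpoint only
    return True


def _accept_loop_edge(i, j, pts, existing, lines, clearance, min_angle) -> bool:
    """Admission test for a reticulating extra edge.

    A realistic mesh loop encloses a wide face: the new edge must not
    short-circuit a 2-hop path (graph distance >= 3), must meet incident
    edges at a reasonable angle, must not cross anything, and must keep a
    clearance from unrelated nodes and edges so that rendered strokes stay
    distinguishable.
    """
    adj: dict[int, set[int]] = {}
    for u, v in existing:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    # hop distance i -> j, early exit at 3
    frontier, dist, found = {i}, 0, False
    seen = {i}
    while frontier and dist < 3 and not found:
        dist += 1
        frontier = {w for u in frontier for w in adj.get(u, ())} - seen
        seen |= frontier
        found = j in frontier
    if found:
        return False
    ls = LineString([pts[i], pts[j]])
    d_new = pts[j] - pts[i]
    for e, other in lines.items():
        shared = {i, j} & set(e)
        if shared:
            # angle at the shared endpoint must stay wide
            (s,) = shared
            o = e[0] if e[1] == s else e[1]
            d_old = pts[o] - pts[s]
            d_cand = d_new if s == i else -d_new
            cosang = float(d_cand @ d_old) / (
                np.hypot(*d_cand) * np.hypot(*d_old)
            )
            if math.acos(np.clip(cosang, -1, 1)) < min_angle:
                return False
            if _segments_cross(ls, other, shared=True):
                return False
        else:
            if ls.distance(other) < 0.8 * clearance:
                return False
    for k in range(len(pts)):
        if k not in (i, j) and ls.distance(Point(pts[k])) < clearance:
            return False
    return True


def generate_network(params: SyntheticNetworkParams) -> nx.MultiGraph:
    """Seeded random planar network with tapering radii.

    Deterministic given ``params.seed``.  ``loop_fraction = 0`` yields a
    tree (E = N - 1); extra loop edges are the shortest candidate pairs
    that neither cross existing edges nor pass close to unrelated nodes.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.extent
    margin = params.radius_range[1] + 8.0
    pts = _sample_points(rng, params.n_points, params.extent, margin)

    dm = distance_matrix(pts, pts)
    mst = minimum_spanning_tree(dm).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(mst.row, mst.col)]
    edges = [(min(u, v), max(u, v)) for u, v in edges]

    n_extra = int(math.floor(params.loop_fraction * params.n_points))
    if n_extra > 0:
        existing = set(edges)
        lines = {e: LineString([pts[e[0]], pts[e[1]]]) for e in edges}
        clearance = 2.5 * params.radius_range[1]
        min_angle = math.radians(35.0)
        candidates = sorted(
            (
                (dm[i, j], i, j)
                for i in range(params.n_points)
                for j in range(i + 1, params.n_points)
                if (i, j) not in existing
            ),
        )
        added = 0
        for _, i, j in candidates:
            if added >= n_extra:
                break
            if _accept_loop_edge(i, j, pts, existing, lines, clearance, min_angle):
                edges.append((i, j))
                existing.add((i, j))
                lines[(i, j)] = LineString([pts[i], pts[j]])
                added += 1

    # radii taper with hop distance from a root near the center
    adj: dict[int, list[int]] = {i: [] for i in range(params.n_points)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    center = pts.mean(axis=0)
    root = int(np.argmin(np.hypot(*(pts - center).T)))
    depth = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in depth:
                    depth[v] = depth[u] + 1
                    nxt.append(v)
        frontier = nxt
    max_depth = max(depth.values()) or 1
    rmin, rmax = params.radius_range
    node_radius = {
        i: rmax - (rmax - rmin) * depth[i] / max_depth for i in range(params.n_points)
    }

    g = nx.MultiGraph()
    g.graph["image_shape"] = (h, w)
    for i, (x, y) in enumerate(pts):
        g.add_node(i, x=float(x), y=float(y), radius=float(node_radius[i]), kind="tip")
    for u, v in sorted(edges):
        pu, pv = pts[u], pts[v]
        g.add_edge(
            u,
            v,
            trajectory=[tuple(map(float, pu)), tuple(map(float, pv))],
            length=float(np.hypot(*(pv - pu))),
            radius=(node_radius[u] + node_radius[v]) / 2.0,
            n_triangles=0,
        )
    return graph_ops.update_kinds(g)


# ---------------------------------------------------------------------------
# rendering


def correlated_noise(
    shape: tuple[int, int], correlation_length: float, amplitude: float, seed: int
) -> np.ndarray:
    """Zero-mean Gaussian noise field with the given autocorrelation scale.

    White noise is convolved with a Gaussian kernel of scale
    ``correlation_length`` and rescaled to standard deviation
    ``amplitude``; correlation length 0 gives plain white noise.
    """
    if amplitude == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    if correlation_length > 0:
        fieldv = ndimage.gaussian_filter(white, correlation_length, mode="reflect")
    else:
        fieldv = white
    fieldv -= fieldv.mean()
    std = fieldv.std()
    if std > 0:
        fieldv *= amplitude / std
    return fieldv


def _stroke(canvas: np.ndarray, p, q, radius: float, value: float) -> None:
    """Max-composite a stroked segment (round caps) onto a float canvas."""
    h, w = canvas.shape
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    x0 = max(int(math.floor(min(p[0], q[0]) - radius - 1)), 0)
    x1 = min(int(math.ceil(max(p[0], q[0]) + radius + 1)), w - 1)
    y0 = max(int(math.floor(min(p[1], q[1]) - radius - 1)), 0)
    y1 = min(int(math.ceil(max(p[1], q[1]) + radius + 1)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1)[None, :]
    ys = np.arange(y0, y1 + 1)[:, None]
    d = q - p
    l2 = float(d @ d)
    if l2 == 0:
        distsq = (xs - p[0]) ** 2 + (ys - p[1]) ** 2
    else:
        t = np.clip(((xs - p[0]) * d[0] + (ys - p[1]) * d[1]) / l2, 0.0, 1.0)
        distsq = (xs - (p[0] + t * d[0])) ** 2 + (ys - (p[1] + t * d[1])) ** 2
    mask = distsq <= radius * radius
    region = canvas[y0 : y1 + 1, x0 : x1 + 1]
    np.maximum(region, np.where(mask, value, 0.0), out=region)


def rasterize_graph(
    g: nx.MultiGraph, shape: tuple[int, int], scale: float = 1.0
) -> np.ndarray:
    """Binary raster of a graph: each edge stroked at its radius."""
    hh = int(round(shape[0] * scale))
    ww = int(round(shape[1] * scale))
    canvas = np.zeros((hh, ww))
    for u, v, k, d in sorted(g.edges(keys=True, data=True), key=lambda e: e[:3]):
        traj = np.asarray(d["trajectory"], dtype=float) * scale
        r = d["radius"] * scale
        for a, b in zip(traj[:-1], traj[1:]):
            _stroke(canvas, a, b, r, 1.0)
    return canvas > 0


def render_network(
    g: nx.MultiGraph, rp: RenderParams, shape: tuple[int, int]
) -> np.ndarray:
    """Grayscale image of a network on a correlated-noise background.

    Each edge is stroked at thickness 2 x radius with an intensity drawn
    uniformly from ``edge_intensity_range`` (per edge, seeded), composited
    over the noise background, then Gaussian-blurred.  Deterministic given
    ``rp.seed``; output clipped to [0, 1].
    """
    rng = np.random.default_rng(rp.seed)
    layer = np.zeros(shape)
    lo, hi = rp.edge_intensity_range
    for u, v, k, d in sorted(g.edges(keys=True, data=True), key=lambda e: e[:3]):
        intensity = float(rng.uniform(lo, hi))
        traj = np.asarray(d["trajectory"], dtype=float)
        for a, b in zip(traj[:-1], traj[1:]):
            _stroke(layer, a, b, d["radius"], intensity)
    noise = correlated_noise(
        shape,
        rp.noise_correlation_length,
        rp.noise_amplitude,
        (rp.seed + 7919) % 2**31,
    )
    img = np.clip(layer + noise, 0.0, 1.0)
    if rp.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, rp.blur_sigma, mode="reflect")
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# error metrics


def sigma(s_original: float, s_validated: float) -> float:
    """Relative extraction error |S_o - S_v| / S_o of one observable."""
    if s_original == 0:
        raise ValueError("sigma undefined for a zero reference observable")
    return abs(s_original - s_validated) / abs(s_original)


def pixel_difference(
    g1: nx.MultiGraph, g2: nx.MultiGraph, raster_scale: float = 1.0
) -> float:
    """Pixel-wise difference of the rasterized graphs, no alignment applied.

    Both graphs are stroked identically at ``raster_scale`` px per model
    unit; D = sum |I1 - I2| / (# foreground pixels of I1).  Zero iff the
    rasters coincide.
    """
    shape = g1.graph.get("image_shape")
    if shape is None:
        coords = np.array(
            [[d["y"], d["x"]] for gg in (g1, g2) for _, d in gg.nodes(data=True)]
        )
        radii = [d["radius"] for gg in (g1, g2) for _, _, d in gg.edges(data=True)]
        pad = (max(radii) if radii else 1.0) + 2
        shape = (
            int(math.ceil(coords[:, 0].max() + pad)),
            int(math.ceil(coords[:, 1].max() + pad)),
        )
    i1 = rasterize_graph(g1, shape, raster_scale).astype(float)
    i2 = rasterize_graph(g2, shape, raster_scale).astype(float)
    n1 = i1.sum()
    if n1 == 0:
        raise ValueError("first graph rasterizes to an empty image")
    return float(np.abs(i1 - i2).sum() / n1)


# ---------------------------------------------------------------------------
# the round trip


@dataclass
class ValidationRow:
    seed: int
    sigma_n: float
    sigma_l: float
    sigma_rbar: float
    sigma_ratio: float
    pixel_diff: float


@dataclass
class ValidationReport:
    rows: list[ValidationRow]
    failures: list[tuple[int, str]]

    OBSERVABLES = ("sigma_n", "sigma_l", "sigma_rbar", "sigma_ratio", "pixel_diff")

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean and standard deviation of each error over the networks."""
        out = {}
        for name in self.OBSERVABLES:
            vals = np.array([getattr(r, name) for r in self.rows], dtype=float)
            out[name] = (float(vals.mean()), float(vals.std())) if len(vals) else (
                math.nan,
                math.nan,
            )
        return out


def roundtrip_once(
    seed: int,
    net_params: SyntheticNetworkParams,
    render_params: RenderParams,
    extract_params: ExtractParams,
    raster_scale: float = 1.0,
) -> ValidationRow:
    """One generate -> render -> segment -> re-extract -> compare pass."""
    np_ = replace(net_params, seed=seed)
    rp = replace(render_params, seed=seed)
    g0 = generate_network(np_)
    h, w = np_.extent[1], np_.extent[0]
    img = render_network(g0, rp, (h, w))
    binary = largest_component(binarize_adaptive(img, extract_params.segmentation))
    g1 = extract_network(
        binary,
        p=extract_params.p,
        r=extract_params.r,
        tolerance=extract_params.tolerance,
        max_segment=extract_params.max_segment,
    )
    # compare at redundancy 0 so node counts are topology-comparable
    s0 = compute_stats(graph_ops.reduce_redundancy(g0, 0))
    s1 = compute_stats(graph_ops.reduce_redundancy(g1, 0))
    return ValidationRow(
        seed=seed,
        sigma_n=sigma(s0.n_nodes, s1.n_nodes),
        sigma_l=sigma(s0.total_length, s1.total_length),
        sigma_rbar=sigma(s0.mean_radius, s1.mean_radius),
        sigma_ratio=sigma(s0.radius_ratio, s1.radius_ratio),
        pixel_diff=pixel_difference(g0, g1, raster_scale),
    )


def run_validation(
    n_networks: int = 30,
    net_params: SyntheticNetworkParams | None = None,
    render_params: RenderParams | None = None,
    extract_params: ExtractParams | None = None,
    seeds: list[int] | None = None,
    raster_scale: float = 1.0,
) -> ValidationReport:
    """Round-trip validation over ``n_networks`` seeded synthetic networks.

    Fully deterministic given the seed list (default ``1..n_networks``).
    A failure in any stage of one network is recorded and excluded from
    the aggregate with a warning.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    net_params = net_params or SyntheticNetworkParams()
    render_params = render_params or RenderParams()
    extract_params = extract_params or ExtractParams()
    seeds = list(seeds) if seeds is not None else list(range(1, n_networks + 1))
    rows, failures = [], []
    for seed in seeds:
        try:
            rows.append(
                roundtrip_once(
                    seed, net_params, render_params, extract_params, raster_scale
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-network failures are data
            failures.append((seed, str(exc)))
            warnings.warn(f"validation network seed={seed} failed: {exc}")
    return ValidationReport(rows=rows, failures=failures)


def write_report(report: ValidationReport, path) -> None:
    """TSV report: one row per network plus mean/std aggregate rows."""
    from pathlib import Path

    lines = ["seed\tsigma_n\tsigma_l\tsigma_rbar\tsigma_ratio\tpixel_diff"]
    for r in report.rows:
        lines.append(
            f"{r.seed}\t{r.sigma_n:.6g}\t{r.sigma_l:.6g}\t{r.sigma_rbar:.6g}"
            f"\t{r.sigma_ratio:.6g}\t{r.pixel_diff:.6g}"
        )
    agg = report.aggregate()
    for stat, idx in (("mean", 0), ("std", 1)):
        vals = "\t".join(f"{agg[name][idx]:.6g}" for name in report.OBSERVABLES)
        lines.append(f"{stat}\t{vals}")
    lines.append(f"# failures\t{len(report.failures)}")
    Path(path).write_text("\n".join(lines) + "\n")
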