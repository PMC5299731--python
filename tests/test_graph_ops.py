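"""Graph post-processing: pruning, redundancy, cycles, editing primitives."""

import numpy as np
import pytest

from netvec import graph_ops
from netvec.graph_ops import (
    GraphOpError,
    add_edge,
    add_node,
    apply_edits,
    find_cycles,
    keep_largest_graph_component,
    prune,
    reduce_redundancy,
    remove_edge,
    remove_node,
    total_length,
)
from netvec.validation import SyntheticNetworkParams, generate_network
from netvec.vectorization import distance_map

from conftest import make_grid_graph, make_h_graph, make_y_graph


class TestPrune:
    def test_p_zero_is_identity(self, y_graph):
        out = prune(y_graph, 0)
        assert set(out.nodes) == set(y_graph.nodes)
        assert out.number_of_edges() == y_graph.number_of_edges()

    def test_short_arm_removed_and_arms_merged(self):
        g = make_y_graph((10, 10, 2))
        out = reduce_redundancy(prune(g, 3), 0)
        # the 2-triangle arm is gone; the two long arms merge to one edge
        assert out.number_of_edges() == 1
        (_, _, d), = out.edges(data=True)
        assert d["n_triangles"] == 20
        kinds = [dd["kind"] for _, dd in out.nodes(data=True)]
        assert kinds.count("junction") == 0
        assert kinds.count("tip") == 2

    def test_huge_p_keeps_single_chain_of_tree(self):
        g = make_y_graph((10, 10, 2))
        out = reduce_redundancy(prune(g, 10_000), 0)
        # a path component is never pruned away entirely
        assert out.number_of_edges() >= 1
        assert total_length(out) > 0

    def test_junction_core_never_removed(self, grid_graph):
        out = prune(grid_graph, 10_000)
        # the grid has no dangling branches: nothing to prune
        assert out.number_of_edges() == grid_graph.number_of_edges()

    def test_iterates_to_fixed_point(self):
        # a short arm hidden behind another short arm: single-pass pruning
        # would leave the inner one
        g = make_y_graph((10, 2, 2))
        out = reduce_redundancy(prune(g, 3), 0)
        assert out.number_of_edges() == 1

    def test_negative_p_rejected(self, y_graph):
        with pytest.raises(GraphOpError):
            prune(y_graph, -1)

    @pytest.mark.parametrize("maker", [make_y_graph, make_h_graph, make_grid_graph])
    def test_idempotent(self, maker):
        g = maker()
        for p in (0, 1, 3, 10):
            once = prune(g, p)
            twice = prune(once, p)
            assert set(once.nodes) == set(twice.nodes)
            assert once.number_of_edges() == twice.number_of_edges()
            assert total_length(once) == pytest.approx(total_length(twice))

    @pytest.mark.parametrize("maker", [make_y_graph, make_h_graph, make_grid_graph])
    def test_monotone_in_p(self, maker):
        g = maker()
        def surviving_points(gp):
            pts = set()
            for *_, d in gp.edges(data=True):
                for x, y in d["trajectory"]:
                    pts.add((round(x, 6), round(y, 6)))
            return pts

        previous = None
        for p in (0, 1, 3, 10):
            pts = surviving_points(prune(g, p))
            if previous is not None:
                assert pts <= previous
            previous = pts


class TestReduceRedundancy:
    def test_r2_is_identity(self, y_graph):
        out = reduce_redundancy(y_graph, 2)
        assert set(out.nodes) == set(y_graph.nodes)
        assert out.number_of_edges() == y_graph.number_of_edges()

    def test_path_r0_two_nodes_one_edge(self, path_graph):
        out = reduce_redundancy(path_graph, 0)
        assert out.number_of_nodes() == 2
        assert out.number_of_edges() == 1
        assert total_length(out) == pytest.approx(40.0)

    def test_path_r1_keeps_alternate_interior_nodes(self, path_graph):
        out = reduce_redundancy(path_graph, 1)
        # interior nodes 1..3 -> keep 1st and 3rd (ids 1, 3)
        assert sorted(out.nodes) == [0, 1, 3, 4]
        assert total_length(out) == pytest.approx(40.0)

    def test_r0_leaves_no_interior_degree_two_nodes(self, h_graph):
        out = reduce_redundancy(h_graph, 0)
        for n in out.nodes:
            if out.degree(n) == 2 and not out.has_edge(n, n):
                pytest.fail(f"degree-2 node {n} survived r=0")

    def test_pure_cycle_keeps_anchor(self):
        from conftest import make_ring_graph

        g = make_ring_graph(8)
        out = reduce_redundancy(g, 0)
        assert out.number_of_nodes() == 1
        (n,) = out.nodes
        assert out.has_edge(n, n)
        assert total_length(out) == pytest.approx(total_length(g), rel=1e-9)

    def test_invalid_level_rejected(self, path_graph):
        with pytest.raises(GraphOpError):
            reduce_redundancy(path_graph, 3)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("r", [0, 1, 2])
    def test_total_length_conserved_on_random_networks(self, seed, r):
        g = generate_network(
            SyntheticNetworkParams(n_points=40, extent=(256, 256), seed=seed)
        )
        out = reduce_redundancy(g, r)
        assert total_length(out) == pytest.approx(total_length(g), rel=1e-9)

    def test_radius_is_length_weighted_after_merge(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_node(0, x=0.0, y=0.0, radius=1.0, kind="tip")
        g.add_node(1, x=10.0, y=0.0, radius=1.0, kind="redundant")
        g.add_node(2, x=40.0, y=0.0, radius=1.0, kind="tip")
        g.add_edge(0, 1, trajectory=[(0.0, 0.0), (10.0, 0.0)], length=10.0,
                   radius=2.0, n_triangles=1)
        g.add_edge(1, 2, trajectory=[(10.0, 0.0), (40.0, 0.0)], length=30.0,
                   radius=4.0, n_triangles=3)
        out = reduce_redundancy(g, 0)
        (_, _, d), = out.edges(data=True)
        assert d["radius"] == pytest.approx((2 * 10 + 4 * 30) / 40)
        assert d["n_triangles"] == 4
        assert d["trajectory"] == [(0.0, 0.0), (10.0, 0.0), (40.0, 0.0)]


class TestFindCycles:
    def test_tree_has_no_cycles(self, y_graph):
        assert find_cycles(y_graph) == []

    def test_square_loop_single_cycle(self):
        from conftest import make_ring_graph

        (cycle,) = find_cycles(make_ring_graph(4))
        assert len(cycle) == 4

    def test_two_loops_sharing_a_node(self):
        import networkx as nx

        # two triangles sharing node 0
        g = nx.MultiGraph()
        coords = {0: (0, 0), 1: (1, 0), 2: (1, 1), 3: (-1, 0), 4: (-1, 1)}
        for n, (x, y) in coords.items():
            g.add_node(n, x=float(x), y=float(y), radius=1.0, kind="redundant")
        for u, v in [(0, 1), (1, 2), (2, 0), (0, 3), (3, 4), (4, 0)]:
            g.add_edge(u, v, trajectory=[
                (g.nodes[u]["x"], g.nodes[u]["y"]),
                (g.nodes[v]["x"], g.nodes[v]["y"]),
            ], length=1.0, radius=1.0, n_triangles=0)
        graph_ops.update_kinds(g)
        assert len(find_cycles(g)) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_cycle_count_equals_cyclomatic_number(self, seed):
        import networkx as nx

        g = generate_network(
            SyntheticNetworkParams(n_points=50, extent=(256, 256), seed=seed)
        )
        dim = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
        assert len(find_cycles(g)) == dim

    def test_self_loop_counts_as_cycle(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_node(0, x=0.0, y=0.0, radius=1.0, kind="redundant")
        g.add_edge(0, 0, trajectory=[(0.0, 0.0), (0.0, 0.0)], length=5.0,
                   radius=1.0, n_triangles=2)
        assert find_cycles(g) == [[0]]


class TestEditing:
    def test_remove_tip_removes_its_edge(self, y_graph):
        tip = next(n for n in y_graph if y_graph.degree(n) == 1)
        out = remove_node(y_graph, tip)
        assert tip not in out
        assert out.number_of_edges() == y_graph.number_of_edges() - 1

    def test_remove_junction_disconnects(self, y_graph):
        import networkx as nx

        out = remove_node(y_graph, 0)  # the hub
        assert nx.number_connected_components(out) == 3

    def test_remove_unknown_node_raises(self, y_graph):
        with pytest.raises(GraphOpError):
            remove_node(y_graph, 10_000)

    def test_add_node_measures_radius_from_dmap(self, disk_mask):
        import networkx as nx

        dmap = distance_map(disk_mask)
        g = nx.MultiGraph()
        g, nid = add_node(g, 20.0, 20.0, dmap)
        assert 9 <= g.nodes[nid]["radius"] <= 10.5
        g, nid2 = add_node(g, 0.0, 0.0, dmap)
        assert g.nodes[nid2]["radius"] == 0.0  # background pixel
        assert nid2 == nid + 1

    def test_add_node_out_of_bounds_raises(self, disk_mask):
        import networkx as nx

        with pytest.raises(GraphOpError):
            add_node(nx.MultiGraph(), 500.0, 2.0, distance_map(disk_mask))

    def test_add_edge_straight_line_semantics(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_node(0, x=0.0, y=0.0, radius=2.0, kind="tip")
        g.add_node(1, x=3.0, y=4.0, radius=4.0, kind="tip")
        out = add_edge(g, 0, 1)
        (_, _, d), = out.edges(data=True)
        assert d["length"] == pytest.approx(5.0)
        assert d["radius"] == pytest.approx(3.0)
        assert d["n_triangles"] == 0

    def test_add_duplicate_edge_raises(self, path_graph):
        with pytest.raises(GraphOpError):
            add_edge(path_graph, 0, 1)

    def test_add_then_remove_edge_restores_graph(self):
        import networkx as nx

        g = nx.MultiGraph()
        g.add_node(0, x=0.0, y=0.0, radius=1.0, kind="tip")
        g.add_node(1, x=5.0, y=0.0, radius=1.0, kind="tip")
        out = remove_edge(add_edge(g, 0, 1), 0, 1)
        assert out.number_of_edges() == 0
        assert set(out.nodes) == {0, 1}

    def test_remove_missing_edge_raises(self, y_graph):
        tips = [n for n in y_graph if y_graph.degree(n) == 1]
        with pytest.raises(GraphOpError):
            remove_edge(y_graph, tips[0], tips[1])

    def test_apply_edits_script(self, disk_mask):
        import networkx as nx

        g = nx.MultiGraph()
        dmap = distance_map(disk_mask)
        script = [
            {"op": "add_node", "x": 20.0, "y": 20.0},
            {"op": "add_node", "x": 25.0, "y": 20.0},
            {"op": "add_edge", "u": 0, "v": 1},
        ]
        out = apply_edits(g, script, dmap=dmap)
        assert out.number_of_edges() == 1
        with pytest.raises(GraphOpError):
            apply_edits(out, [{"op": "frobnicate"}])


class TestKeepLargestComponent:
    def test_connected_graph_unchanged(self, y_graph):
        out = keep_largest_graph_component(y_graph)
        assert set(out.nodes) == set(y_graph.nodes)

    def test_keeps_longest_component(self, y_graph):
        import networkx as nx
        from conftest import add_chain

        g = y_graph.copy()
        add_chain(g, 1000, [(200.0, 200.0), (201.0, 200.0)])  # 1-px crumb
        graph_ops.update_kinds(g)
        out = keep_largest_graph_component(g)
        assert 1000 not in out

    def test_tie_broken_by_node_count(self):
        import networkx as nx
        from conftest import add_chain

        g = nx.MultiGraph()
        add_chain(g, 0, [(0.0, 0.0), (10.0, 0.0)])  # 2 nodes, length 10
        add_chain(g, 10, [(0.0, 50.0), (5.0, 50.0), (10.0, 50.0)])  # 3 nodes, length 10
        graph_ops.update_kinds(g)
        out = keep_largest_graph_component(g)
        assert set(out.nodes) == {10, 11, 12}

    def test_empty_graph_raises(self):
        import networkx as nx

        with pytest.raises(GraphOpError):
            keep_largest_graph_component(nx.MultiGraph())
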