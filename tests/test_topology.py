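import networkx as nx
import numpy as np
import pytest

from airway_topo import (
    Parameters,
    SkeletonTree,
    TopologyGraph,
    ValidationError,
    build_graph,
    extract_dominant,
    junction_degree_histogram,
    merge_close_junctions,
)


def _y_dominant(trunk=20, arm_long=15, arm_short=10):
    """Dominant skeleton of a unit-edge Y tree (junction at end of trunk)."""
    coords = [[i, 50, 0] for i in range(trunk + 1)]
    coords += [[trunk, 50 + j, 0] for j in range(1, arm_long + 1)]
    coords += [[trunk, 50 - j, 0] for j in range(1, arm_short + 1)]
    edges = [(i, i + 1) for i in range(trunk)]
    edges += [(trunk, trunk + 1)]
    edges += [(trunk + j, trunk + j + 1) for j in range(1, arm_long)]
    base = trunk + arm_long
    edges += [(trunk, base + 1)]
    edges += [(base + j, base + j + 1) for j in range(1, arm_short)]
    tree = SkeletonTree.build(coords, edges)
    seed = int(np.argmax([tuple(p) == (0, 50, 0) for p in tree.points]))
    return extract_dominant(tree, seed, Parameters(min_branch_length=3))


def _manual_graph(nodes, edges, entrance=0, main_len=None) -> TopologyGraph:
    g = nx.Graph()
    for n, kind, arc in nodes:
        g.add_node(n, kind=kind, position=(float(arc), 0.0, 0.0), arc_length=float(arc))
    for u, v, length in edges:
        g.add_edge(u, v, length=float(length))
    if main_len is None:
        main_len = max(arc for _, _, arc in nodes)
    return TopologyGraph(g, entrance, float(main_len))


class TestBuildGraph:
    def test_single_path(self):
        coords = [[i, 0, 0] for i in range(36)]
        tree = SkeletonTree.build(coords, [(i, i + 1) for i in range(35)])
        dom = extract_dominant(tree, 0, Parameters(min_branch_length=3))
        tg = build_graph(dom)
        assert tg.graph.number_of_nodes() == 2
        assert tg.graph.number_of_edges() == 1
        (length,) = [d["length"] for _, _, d in tg.graph.edges(data=True)]
        assert length == pytest.approx(35.0)
        kinds = sorted(d["kind"] for _, d in tg.graph.nodes(data=True))
        assert kinds == ["endpoint", "entrance"]

    def test_y_graph_edge_lengths(self):
        tg = build_graph(_y_dominant())
        assert tg.graph.number_of_nodes() == 4
        assert tg.graph.number_of_edges() == 3
        lengths = sorted(d["length"] for _, _, d in tg.graph.edges(data=True))
        assert lengths == pytest.approx([10.0, 15.0, 20.0])
        assert tg.main_path_length == pytest.approx(35.0)
        (jn,) = tg.junction_nodes()
        assert tg.graph.degree(jn) == 3
        assert tg.graph.nodes[jn]["arc_length"] == pytest.approx(20.0)

    def test_single_node_tree(self):
        tree = SkeletonTree.build([[5, 5, 5]], [])
        dom = extract_dominant(tree, 0, Parameters(min_branch_length=1))
        tg = build_graph(dom)
        assert tg.graph.number_of_nodes() == 1
        assert tg.graph.number_of_edges() == 0

    def test_edge_lengths_conserve_dominant_length(self):
        dom = _y_dominant()
        tg = build_graph(dom)
        assert tg.total_length == pytest.approx(dom.total_length)


class TestMergeCloseJunctions:
    def _two_junction_graph(self, gap=1.0):
        return _manual_graph(
            nodes=[
                (0, "entrance", 0.0),
                (1, "junction", 10.0),
                (2, "junction", 10.0 + gap),
                (3, "endpoint", 30.0),
                (4, "endpoint", 20.0),
                (5, "endpoint", 21.0),
            ],
            edges=[
                (0, 1, 10.0),
                (1, 2, gap),
                (2, 3, 30.0 - 10.0 - gap),
                (1, 4, 10.0),
                (2, 5, 11.0 - gap),
            ],
            main_len=30.0,
        )

    def test_two_close_junctions_merge_to_degree_four(self):
        merged = merge_close_junctions(self._two_junction_graph(1.0), 3.0)
        (jn,) = merged.junction_nodes()
        assert merged.graph.degree(jn) == 4

    def test_threshold_not_met_leaves_graph_unchanged(self):
        tg = self._two_junction_graph(1.0)
        merged = merge_close_junctions(tg, 0.5)
        assert nx.utils.graphs_equal(merged.graph, tg.graph)

    def test_chain_of_three_junctions_merges_to_degree_five(self):
        tg = _manual_graph(
            nodes=[
                (0, "entrance", 0.0),
                (1, "junction", 10.0),
                (2, "junction", 11.0),
                (3, "junction", 12.0),
                (4, "endpoint", 40.0),
                (5, "endpoint", 20.0),
                (6, "endpoint", 21.0),
                (7, "endpoint", 22.0),
            ],
            edges=[
                (0, 1, 10.0),
                (1, 2, 1.0),
                (2, 3, 1.0),
                (3, 4, 28.0),
                (1, 5, 10.0),
                (2, 6, 10.0),
                (3, 7, 10.0),
            ],
            main_len=40.0,
        )
        merged = merge_close_junctions(tg, 3.0)
        (jn,) = merged.junction_nodes()
        assert merged.graph.degree(jn) == 5

    def test_idempotent_and_tree_preserving(self):
        tg = self._two_junction_graph(1.0)
        once = merge_close_junctions(tg, 3.0)
        twice = merge_close_junctions(once, 3.0)
        assert nx.utils.graphs_equal(once.graph, twice.graph)
        assert nx.is_tree(once.graph)
        # node count decreases by exactly one per contraction
        assert tg.graph.number_of_nodes() - once.graph.number_of_nodes() == 1

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            merge_close_junctions(self._two_junction_graph(), -1.0)


class TestJunctionDegreeHistogram:
    def _side_branch_graph(self, at_fraction):
        arc = 100.0 * at_fraction
        return _manual_graph(
            nodes=[
                (0, "entrance", 0.0),
                (1, "junction", arc),
                (2, "endpoint", 100.0),
                (3, "endpoint", arc + 20.0),
            ],
            edges=[(0, 1, arc), (1, 2, 100.0 - arc), (1, 3, 20.0)],
            main_len=100.0,
        )

    def test_single_side_branch_is_a_three_junction(self):
        feat = junction_degree_histogram(self._side_branch_graph(0.3), 0.75)
        assert feat.counts == {3: 1}

    def test_junction_beyond_cutoff_not_counted(self):
        feat = junction_degree_histogram(self._side_branch_graph(0.9), 0.75)
        assert feat.counts == {}

    def test_merged_double_branch_counts_as_four_junction(self):
        tg = TestMergeCloseJunctions()._two_junction_graph(1.0)
        merged = merge_close_junctions(tg, 3.0)
        feat = junction_degree_histogram(merged, 0.5)
        assert feat.counts == {4: 1}

    def test_full_fraction_counts_every_junction(self):
        tg = TestMergeCloseJunctions()._two_junction_graph(5.0)
        feat = junction_degree_histogram(tg, 1.0)
        assert feat.total == len(tg.junction_nodes())

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.2])
    def test_fraction_out_of_range_rejected(self, fraction):
        with pytest.raises(ValidationError):
            junction_degree_histogram(self._side_branch_graph(0.3), fraction)
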