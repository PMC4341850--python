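import numpy as np
import pytest

from airway_topo import (
    Parameters,
    ValidationError,
    backtrack_path,
    extract_dominant,
    farthest_point,
    geodesic_distance_transform,
)
from .conftest import chain_tree, random_skeleton_tree


@pytest.fixture
def chain3():
    # A(0,0,0) - B(1,0,0) - C(2,0,0), unit edges
    return chain_tree([[0, 0, 0], [1, 0, 0], [2, 0, 0]])


def _y_tree(trunk=20, arm_long=15, arm_short=10):
    """Trunk along x, fork at its end, two arms along +/-y (unit edges)."""
    coords = [[i, 50, 0] for i in range(trunk + 1)]
    fork = trunk
    coords += [[trunk, 50 + j, 0] for j in range(1, arm_long + 1)]
    coords += [[trunk, 50 - j, 0] for j in range(1, arm_short + 1)]
    edges = [(i, i + 1) for i in range(trunk)]
    edges += [(fork, trunk + 1)] + [(trunk + j, trunk + j + 1) for j in range(1, arm_long)]
    base = trunk + arm_long
    edges += [(fork, base + 1)] + [(base + j, base + j + 1) for j in range(1, arm_short)]
    from airway_topo import SkeletonTree

    return SkeletonTree.build(coords, edges)


class TestGeodesicDistanceTransform:
    def test_unit_chain_distances_and_predecessors(self, chain3):
        field = geodesic_distance_transform(chain3, {0})
        assert field.distance[2] == pytest.approx(2.0)
        assert field.predecessor[2] == 1
        assert field.distance[0] == 0.0

    def test_all_nodes_as_sources_gives_zero(self, chain3):
        field = geodesic_distance_transform(chain3, {0, 1, 2})
        assert np.all(field.distance == 0.0)

    def test_source_outside_tree_raises(self, chain3):
        with pytest.raises(ValidationError):
            geodesic_distance_transform(chain3, {99})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_networkx_oracle_on_random_trees(self, seed):
        from ._oracles import geodesic_oracle

        rng = np.random.default_rng(seed)
        tree = random_skeleton_tree(rng, 50)
        sources = {int(s) for s in rng.integers(0, 50, size=3)}
        field = geodesic_distance_transform(tree, sources)
        oracle = geodesic_oracle(tree, sources)
        for node, expected in oracle.items():
            assert field.distance[node] == pytest.approx(expected)


class TestFarthestPointAndBacktrack:
    def test_chain_farthest_is_far_end(self, chain3):
        field = geodesic_distance_transform(chain3, {0})
        assert farthest_point(field) == 2

    def test_symmetric_y_tie_breaks_lexicographically(self):
        tree = _y_tree(trunk=4, arm_long=5, arm_short=5)
        fork = next(i for i in range(tree.n_nodes) if tree.degree(i) == 3)
        field = geodesic_distance_transform(tree, {fork})
        tip = farthest_point(field)
        tips = np.where(field.distance == field.distance.max())[0]
        assert len(tips) >= 2  # genuinely tied
        assert tip == tips.min()

    def test_backtrack_chain(self, chain3):
        field = geodesic_distance_transform(chain3, {0})
        path = backtrack_path(field, 2)
        assert path.nodes == [0, 1, 2]
        assert path.length == pytest.approx(2.0)
        assert path.connection_node == 0

    def test_backtrack_source_is_single_node(self, chain3):
        field = geodesic_distance_transform(chain3, {0})
        path = backtrack_path(field, 0)
        assert path.nodes == [0]
        assert path.length == 0.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_backtracked_length_equals_oracle_distance(self, seed):
        from ._oracles import geodesic_oracle

        rng = np.random.default_rng(seed)
        tree = random_skeleton_tree(rng, 40)
        field = geodesic_distance_transform(tree, {0})
        tip = farthest_point(field)
        path = backtrack_path(field, tip)
        assert path.length == pytest.approx(geodesic_oracle(tree, {0})[tip])


class TestExtractDominant:
    def test_straight_chain_single_path_no_junctions(self):
        tree = chain_tree([[i, 0, 0] for i in range(30)])
        dom = extract_dominant(tree, 0, Parameters(min_branch_length=3))
        assert len(dom.paths) == 1
        assert dom.junctions == set()
        assert dom.main_path_length == pytest.approx(29.0)

    def test_y_tree_main_takes_longer_arm(self):
        tree = _y_tree(trunk=20, arm_long=15, arm_short=10)
        seed = int(np.argmax([tuple(p) == (0, 50, 0) for p in tree.points]))
        dom = extract_dominant(tree, seed, Parameters(min_branch_length=3))
        assert len(dom.paths) == 2
        assert dom.main_path_length == pytest.approx(35.0)
        assert dom.paths[1].length == pytest.approx(10.0)
        assert len(dom.junctions) == 1
        (jn,) = dom.junctions
        assert tuple(tree.points[jn]) == (20, 50, 0)

    def test_short_noise_leaf_suppressed(self):
        tree = _y_tree(trunk=20, arm_long=15, arm_short=2)
        seed = int(np.argmax([tuple(p) == (0, 50, 0) for p in tree.points]))
        dom = extract_dominant(tree, seed, Parameters(min_branch_length=3))
        assert len(dom.paths) == 1
        assert dom.junctions == set()

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_main_path_is_max_leaf_geodesic(self, seed):
        from ._oracles import max_leaf_geodesic

        rng = np.random.default_rng(seed)
        tree = random_skeleton_tree(rng, 200)
        dom = extract_dominant(tree, 0, Parameters(min_branch_length=1.0))
        assert dom.main_path_length == pytest.approx(max_leaf_geodesic(tree, 0))

    @pytest.mark.parametrize("seed", [1, 6])
    def test_branch_lengths_non_increasing_and_paths_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_skeleton_tree(rng, 150)
        dom = extract_dominant(tree, 0, Parameters(min_branch_length=1.0))
        lengths = [p.length for p in dom.paths[1:]]
        assert all(a >= b - 1e-9 for a, b in zip(lengths, lengths[1:]))
        seen: set = set()
        for p in dom.paths:
            interior = set(p.nodes) - {p.connection_node}
            assert not (interior & seen)
            seen |= set(p.nodes)

    @pytest.mark.parametrize("seed", [2, 7])
    def test_monotone_in_min_branch_length(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_skeleton_tree(rng, 120)
        counts = [
            len(extract_dominant(tree, 0, Parameters(min_branch_length=t)).paths)
            for t in (0.5, 2.0, 5.0, 10.0, 25.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_under_translation(self):
        rng = np.random.default_rng(12)
        from airway_topo import SkeletonTree

        pts = np.unique(rng.integers(0, 40, size=(60, 3)), axis=0)
        edges = [(i, int(rng.integers(0, i))) for i in range(1, len(pts))]
        t0 = SkeletonTree.build(pts, edges)
        t1 = SkeletonTree.build(pts + 11, edges)
        d0 = extract_dominant(t0, 0, Parameters(min_branch_length=2.0))
        d1 = extract_dominant(t1, 0, Parameters(min_branch_length=2.0))
        assert [p.length for p in d0.paths] == pytest.approx([p.length for p in d1.paths])

    def test_seed_outside_tree_raises(self, chain3):
        with pytest.raises(ValidationError):
            extract_dominant(chain3, 99, Parameters(min_branch_length=1.0))
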