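import numpy as np
import pytest

from airway_topo import (
    PHANTOM_PARAMETERS,
    SkeletonTree,
    generate_tree_spec,
    rasterize_tree,
)
from airway_topo.dominant_skeleton import snap_seed
from airway_topo.pipeline import skeletonize_volume


def random_voxel_points(rng, n, coord_range=60):
    """n distinct random integer voxel triples."""
    pts = rng.integers(0, coord_range, size=(2 * n + 8, 3))
    pts = np.unique(pts, axis=0)
    rng.shuffle(pts)
    assert len(pts) >= n
    return pts[:n]


def random_skeleton_tree(rng, n, coord_range=60) -> SkeletonTree:
    """Random tree over n distinct voxel points (random-attachment edges)."""
    pts = random_voxel_points(rng, n, coord_range)
    edges = [(i, int(rng.integers(0, i))) for i in range(1, n)]
    return SkeletonTree.build(pts, edges)


def chain_tree(coords) -> SkeletonTree:
    """A path tree through the given voxel coordinates, in order."""
    coords = np.asarray(coords)
    return SkeletonTree.build(coords, [(i, i + 1) for i in range(len(coords) - 1)])


class PhantomCase:
    """A phantom with its rasterization and cached skeleton tree."""

    def __init__(self, class_label: str, seed: int):
        self.class_label = class_label
        self.seed = seed
        self.spec = generate_tree_spec(class_label, rng_seed=seed)
        self.volume = rasterize_tree(self.spec)
        self.tree = skeletonize_volume(self.volume, PHANTOM_PARAMETERS.mst_neighbor_count)
        self.seed_node = snap_seed(self.tree, self.spec.entrance_position)


@pytest.fixture(scope="session")
def phantom_corpus():
    """Lazily built cache of phantoms keyed by (class_label, seed)."""
    cache: dict = {}

    def get(class_label: str, seed: int) -> PhantomCase:
        key = (class_label, seed)
        if key not in cache:
            cache[key] = PhantomCase(class_label, seed)
        return cache[key]

    return get
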