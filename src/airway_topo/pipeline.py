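"""End-to-end convenience wrappers: volume -> skeleton -> topology -> features."""

from __future__ import annotations

import numpy as np

from .dominant_skeleton import DominantSkeleton, extract_dominant, snap_seed
from .skeleton3d import SkeletonTree, prim_mst, triaxial_skeleton
from .topology import (
    JunctionFeature,
    TopologyGraph,
    build_graph,
    junction_degree_histogram,
    merge_close_junctions,
)
from .volume_io import LabelVolume, Parameters


def skeletonize_volume(volume: LabelVolume, neighbor_count: int = 26) -> SkeletonTree:
    """Tri-axial slice skeletonization, voxel-wise AND, and MST connection."""
    return prim_mst(triaxial_skeleton(volume), neighbor_count)


def extract_topology(
    volume: LabelVolume, seed_physical, params: Parameters | None = None
) -> TopologyGraph:
    """Full extraction: skeleton tree, dominant branches, merged topology graph.

    ``seed_physical`` is the physical coordinate of the airway entrance and
    is snapped to the nearest skeleton node.
    """
    if params is None:
        params = Parameters()
    tree = skeletonize_volume(volume, params.mst_neighbor_count)
    seed = snap_seed(tree, np.asarray(seed_physical, dtype=float))
    dom = extract_dominant(tree, seed, params)
    graph = build_graph(dom)
    return merge_close_junctions(graph, params.resolve_merge_distance(volume.spacing))


def compute_features(
    volume: LabelVolume,
    seed_physical,
    params: Parameters | None = None,
    sample_id: str = "",
) -> JunctionFeature:
    """Junction-degree histogram of a volume within the main-path fraction."""
    if params is None:
        params = Parameters()
    tg = extract_topology(volume, seed_physical, params)
    return junction_degree_histogram(tg, params.main_path_fraction, sample_id)
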