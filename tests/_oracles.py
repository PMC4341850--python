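"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the MST oracle
enumerates every spanning tree via Prufer sequences, and the geodesic
oracles go through networkx shortest paths on an independently built graph.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform


def exhaustive_mst_weight(phys: np.ndarray) -> float:
    """Minimum spanning-tree weight over *all* spanning trees of K_n.

    Enumerates the n^(n-2) Prufer sequences (vectorized decode), feasible up
    to n = 8, and returns the minimum total edge weight.
    """
    n = len(phys)
    D = squareform(pdist(phys))
    if n == 1:
        return 0.0
    if n == 2:
        return float(D[0, 1])
    seqs = np.array(list(itertools.product(range(n), repeat=n - 2)), dtype=np.int64)
    N = len(seqs)
    deg = np.ones((N, n), dtype=np.int64)
    np.add.at(deg, (np.arange(N)[:, None], seqs), 1)
    alive = np.ones((N, n), dtype=bool)
    w = np.zeros(N)
    rows = np.arange(N)
    for k in range(n - 2):
        leaf = np.argmax((deg == 1) & alive, axis=1)
        s = seqs[:, k]
        w += D[leaf, s]
        alive[rows, leaf] = False
        deg[rows, leaf] -= 1
        deg[rows, s] -= 1
    rem = np.argsort(~((deg == 1) & alive), axis=1)[:, :2]
    w += D[rem[:, 0], rem[:, 1]]
    return float(w.min())


def tree_as_nx(tree) -> nx.Graph:
    """Rebuild a SkeletonTree as a networkx graph for oracle computations."""
    g = nx.Graph()
    g.add_nodes_from(range(tree.n_nodes))
    for i, j, w in tree.edges:
        g.add_edge(i, j, weight=w)
    return g


def geodesic_oracle(tree, sources) -> dict:
    """Multi-source shortest-path distances via networkx."""
    g = tree_as_nx(tree)
    best: dict[int, float] = {}
    for s in sources:
        d = nx.single_source_dijkstra_path_length(g, s, weight="weight")
        for node, dist in d.items():
            if node not in best or dist < best[node]:
                best[node] = dist
    return best


def max_leaf_geodesic(tree, seed: int) -> float:
    """Brute-force maximum geodesic distance from the seed over all leaves."""
    g = tree_as_nx(tree)
    d = nx.single_source_dijkstra_path_length(g, seed, weight="weight")
    leaves = [n for n in g.nodes if g.degree(n) <= 1]
    return max(d[n] for n in leaves)
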