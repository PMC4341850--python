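"""Topological graph reduction and junction-degree features.

The dominant skeleton is reduced to a graph whose nodes are the entrance,
the junctions (branch connection points) and the endpoints (path tips);
edges are the maximal skeleton segments between consecutive such nodes,
weighted by their summed physical length.  Junctions closer than a merge
distance are contracted into single higher-degree junctions: two branches
leaving the main airway at (nearly) the same point form a 4-junction, three
a 5-junction, and so on.  The feature used for classification is the
histogram of junction degrees within a fraction of the main-airway length,
measured as geodesic arc length from the entrance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dominant_skeleton import DominantSkeleton
from .errors import ValidationError


@dataclass
class TopologyGraph:
    """Reduced branch graph of entrance / junction / endpoint nodes.

    Node attributes: ``kind`` in {"entrance", "junction", "endpoint"},
    ``position`` (physical 3-tuple) and ``arc_length`` (geodesic distance to
    the entrance within this graph).  Edge attribute: ``length`` (physical
    branch length).  ``main_path_length`` is the geodesic length of the first
    dominant path.
    """

    graph: nx.Graph
    entrance: int
    main_path_length: float

    def junction_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "junction"]

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def node_kind(self, n) -> str:
        return self.graph.nodes[n]["kind"]


def _recompute_arc_lengths(g: nx.Graph, entrance: int) -> None:
    dist = nx.single_source_dijkstra_path_length(g, entrance, weight="length")
    for n in g.nodes:
        g.nodes[n]["arc_length"] = float(dist[n])


def build_graph(dom: DominantSkeleton) -> TopologyGraph:
    """Reduce a dominant skeleton to its entrance/junction/endpoint graph."""
    tree = dom.tree
    phys = tree.physical

    # adjacency restricted to the dominant paths
    sub: dict[int, dict[int, float]] = {}
    for path in dom.paths:
        for a, b in zip(path.nodes[:-1], path.nodes[1:]):
            sub.setdefault(a, {})[b] = tree.weight(a, b)
            sub.setdefault(b, {})[a] = tree.weight(a, b)
    for path in dom.paths:
        sub.setdefault(path.nodes[0], {})

    tips = {p.nodes[-1] for p in dom.paths}
    key_nodes = {dom.seed_node} | set(dom.junctions) | tips
    # safety: any skeleton node of degree >= 3 inside the dominant subgraph
    # is a branch point even if bookkeeping missed it
    key_nodes |= {n for n, nbrs in sub.items() if len(nbrs) >= 3}

    g = nx.Graph()

    def kind_of(n: int) -> str:
        if n == dom.seed_node:
            return "entrance"
        if n in dom.junctions or len(sub[n]) >= 3:
            return "junction"
        return "endpoint"

    relabel = {n: i for i, n in enumerate(sorted(key_nodes))}
    for n in sorted(key_nodes):
        g.add_node(
            relabel[n],
            kind=kind_of(n),
            position=tuple(float(c) for c in phys[n]),
            arc_length=0.0,
        )

    seen_half_edges = set()
    for start in sorted(key_nodes):
        for nb in sorted(sub.get(start, {})):
            if (start, nb) in seen_half_edges:
                continue
            length = sub[start][nb]
            prev, cur = start, nb
            while cur not in key_nodes:
                nxt = [m for m in sub[cur] if m != prev]
                if len(nxt) != 1:
                    raise ValidationError("non-chain interior node during reduction")
                length += sub[cur][nxt[0]]
                prev, cur = cur, nxt[0]
            seen_half_edges.add((cur, prev))
            g.add_edge(relabel[start], relabel[cur], length=float(length))

    entrance = relabel[dom.seed_node]
    _recompute_arc_lengths(g, entrance)
    return TopologyGraph(g, entrance, float(dom.main_path_length))


def merge_close_junctions(tg: TopologyGraph, merge_distance: float) -> TopologyGraph:
    """Contract junction-junction edges shorter than ``merge_distance``.

    The shortest qualifying edge is contracted first, repeatedly, until no
    junction pair is closer than the threshold (a fixpoint, so the operation
    is idempotent).  A merged node's degree is the sum of the two degrees
    minus 2; its position is the midpoint of the two merged junctions.  The
    contracted edge's length is removed from the total branch length.
    Entrance and endpoint nodes are never merged away.
    """
    if merge_distance < 0:
        raise ValidationError("merge_distance must be >= 0")
    g = tg.graph.copy()
    while True:
        cands = [
            (d["length"], min(u, v), max(u, v))
            for u, v, d in g.edges(data=True)
            if d["length"] < merge_distance
            and g.nodes[u]["kind"] == "junction"
            and g.nodes[v]["kind"] == "junction"
        ]
        if not cands:
            break
        _, keep, drop = min(cands)
        pos = tuple(
            0.5 * (a + b)
            for a, b in zip(g.nodes[keep]["position"], g.nodes[drop]["position"])
        )
        for nb in list(g.neighbors(drop)):
            if nb != keep:
                g.add_edge(keep, nb, length=g.edges[drop, nb]["length"])
        g.remove_node(drop)
        g.nodes[keep]["position"] = pos
    _recompute_arc_lengths(g, tg.entrance)
    return TopologyGraph(g, tg.entrance, tg.main_path_length)


@dataclass
class JunctionFeature:
    """Histogram of junction degrees within a fraction of the main airway."""

    counts: dict  # degree -> count, degrees >= 3
    fraction: float
    sample_id: str = ""

    def get(self, degree: int) -> int:
        return int(self.counts.get(degree, 0))

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_rows(self) -> list:
        return [
            dict(sample_id=self.sample_id, degree=d, count=c, fraction=self.fraction)
            for d, c in sorted(self.counts.items())
        ]


def junction_degree_histogram(
    tg: TopologyGraph, fraction: float, sample_id: str = ""
) -> JunctionFeature:
    """Count junctions per degree within ``fraction`` of the main-path length.

    A junction is counted when its geodesic arc length from the entrance is
    at most ``fraction * main_path_length``.  A single side branch off the
    main airway is a 3-junction (two parts along the main branch plus one
    sideways); two merged side branches form a 4-junction.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    cutoff = fraction * tg.main_path_length
    counts = Counter(
        int(tg.graph.degree(n))
        for n in tg.junction_nodes()
        if tg.graph.nodes[n]["arc_length"] <= cutoff
    )
    return JunctionFeature(dict(sorted(counts.items())), float(fraction), sample_id)
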