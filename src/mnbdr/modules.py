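"""Dense-cluster (module) detection in an interaction network.

The detector follows the classic MCODE scheme: each vertex is weighted by
the density of the highest k-core of its closed neighborhood scaled by the
core number, seeds are grown in decreasing weight order by admitting
neighbors whose weight stays within a fractional cutoff of the seed's, and
a "haircut" prunes grown clusters back to their 2-core.  Clusters smaller
than ``min_size`` (default 5) are discarded.  Each vertex belongs to at
most one module, and module names ``M1, M2, ...`` follow decreasing seed
weight with lexicographic tie-breaks, so output is bit-reproducible and
independent of input edge order.
"""

from __future__ import annotations

import networkx as nx

from .io import ModuleSet

__all__ = ["vertex_weights", "detect_modules"]


def _highest_kcore(subgraph: nx.Graph) -> tuple[int, nx.Graph]:
    """Return (k, core_subgraph) for the highest non-empty k-core."""
    core = nx.core_number(subgraph)
    k = max(core.values())
    nodes = [v for v, c in core.items() if c >= k]
    return k, subgraph.subgraph(nodes)


def vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    """MCODE vertex weighting.

    weight(v) = k * density of the highest k-core of the subgraph induced
    by v and its neighbors.  Vertices with fewer than ``degree_cutoff``
    neighbors (and isolated vertices) get weight 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    weights: dict = {}
    for v in graph.nodes:
        neighbors = list(graph.neighbors(v))
        if len(neighbors) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = graph.subgraph([v, *neighbors])
        k, core = _highest_kcore(closed)
        n = core.number_of_nodes()
        density = 2.0 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        weights[v] = k * density
    return weights


def detect_modules(
    graph: nx.Graph,
    min_size: int = 5,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    degree_cutoff: int = 2,
) -> ModuleSet:
    """Mine vertex-disjoint dense clusters of at least ``min_size`` nodes.

    Growth from a seed admits an unassigned neighbor when its weight is at
    least ``(1 - node_score_cutoff)`` times the seed weight, recursively.
    With ``haircut`` the grown cluster is trimmed to its 2-core, so trees
    and pendant chains never survive.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not 0.0 <= node_score_cutoff <= 1.0:
        raise ValueError("node_score_cutoff must be in [0, 1]")
    weights = vertex_weights(graph, degree_cutoff=degree_cutoff)
    # decreasing weight, lexicographic vertex id on ties
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    clusters: list[tuple[float, str, frozenset]] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        cluster = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for w in sorted(graph.neighbors(v), key=str):
                if w in assigned or w in cluster:
                    continue
                if weights[w] >= threshold:
                    cluster.add(w)
                    frontier.append(w)
        if haircut:
            sub = graph.subgraph(cluster)
            core = nx.core_number(sub) if sub.number_of_edges() else {}
            cluster = {v for v in cluster if core.get(v, 0) >= 2}
        if len(cluster) >= min_size:
            assigned |= cluster
            clusters.append((weights[seed], str(seed), frozenset(cluster)))
        else:
            # seed stays consumed so growth terminates; members remain free
            assigned.add(seed)
    clusters.sort(key=lambda t: (-t[0], t[1]))
    return ModuleSet({f"M{i}": members for i, (_, _, members) in enumerate(clusters, start=1)})
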