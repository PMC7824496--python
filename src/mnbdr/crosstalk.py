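"""Module-network construction via an inter-module edge permutation test.

Two modules "cross-talk" when the number of interaction edges between them
is significantly higher than expected for random gene sets of the same
sizes.  The null draws pairs of disjoint, node-uniform random sets from
the whole filtered network (not degree-matched); the one-sided p-value
uses the +1 pseudo-count convention so it is never exactly zero.  Pairs
with p below ``alpha`` become edges of the module network; modules with no
significant partner remain as isolated nodes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from .io import ModuleSet

__all__ = [
    "ModuleNetwork",
    "inter_edge_count",
    "crosstalk_pvalue",
    "build_module_network",
]


@dataclass
class ModuleNetwork:
    """Graph of modules connected by statistically significant cross-talks."""

    graph: nx.Graph  # nodes: module names; edges carry p_value, observed
    alpha: float = 0.01
    n_perm: int = 1000

    @property
    def module_names(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, dict]]:
        return [(a, b, d) for a, b, d in self.graph.edges(data=True)]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("module_a\tmodule_b\tobserved_count\tp_value\n")
            for a, b, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d['observed']}\t{d['p_value']:.6g}\n")


def inter_edge_count(graph: nx.Graph, a: set, b: set) -> int:
    """Count graph edges with one endpoint in *a* and the other in *b*.

    Each undirected edge is counted once, including edges internal to the
    overlap a ∩ b; with a == b this is the number of edges internal to a.
    """
    if not a or not b:
        raise ValueError("gene sets must be nonempty")
    # every qualifying edge has >= 1 endpoint in the smaller set
    small = a if len(a) <= len(b) else b
    seen: set[frozenset] = set()
    for u in small:
        if u not in graph:
            continue
        for v in graph.neighbors(u):
            if (u in a and v in b) or (u in b and v in a):
                seen.add(frozenset((u, v)))
    return len(seen)


def _pair_seed(rng_seed: int, name_a: str, name_b: str) -> int:
    """Stable per-pair seed, symmetric in the module names."""
    lo, hi = sorted([name_a, name_b])
    digest = hashlib.sha256(f"{rng_seed}|{lo}|{hi}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def crosstalk_pvalue(
    graph: nx.Graph,
    a: set,
    b: set,
    n_perm: int = 1000,
    rng_seed: int = 0,
    pseudocount: bool = True,
) -> tuple[float, int]:
    """One-sided permutation p-value for edge enrichment between *a* and *b*.

    Each of ``n_perm`` draws takes two disjoint uniform random node sets of
    sizes |a| and |b| from the graph's node universe and counts the edges
    between them.  Returns ``(p_value, observed_count)``.  With
    ``pseudocount`` (default) p = (1 + #{null >= obs}) / (1 + n_perm);
    without it, the bare ratio #{null >= obs} / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = np.asarray(sorted(graph.nodes), dtype=object)
    if len(a) + len(b) > len(universe):
        raise ValueError("combined set size exceeds the node universe")
    observed = inter_edge_count(graph, a, b)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    na = len(a)
    for _ in range(n_perm):
        draw = rng.choice(len(universe), size=na + len(b), replace=False)
        ra = set(universe[draw[:na]])
        rb = set(universe[draw[na:]])
        if inter_edge_count(graph, ra, rb) >= observed:
            exceed += 1
    if pseudocount:
        p = (1 + exceed) / (1 + n_perm)
    else:
        p = exceed / n_perm
    return p, observed


def build_module_network(
    graph: nx.Graph,
    modules: ModuleSet,
    alpha: float = 0.01,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> ModuleNetwork:
    """Test every unordered module pair and connect the significant ones.

    Per-pair seeds are derived by hashing ``(rng_seed, module names)`` so
    the result does not depend on iteration order.  All modules appear as
    nodes; edges are exactly the pairs with p < ``alpha`` and carry the
    p-value and observed inter-edge count.
    """
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    net = nx.Graph()
    net.add_nodes_from(modules.names())
    for name_a, name_b in combinations(modules.names(), 2):
        seed = _pair_seed(rng_seed, name_a, name_b)
        p, observed = crosstalk_pvalue(
            graph, set(modules[name_a]), set(modules[name_b]), n_perm=n_perm, rng_seed=seed
        )
        if p < alpha:
            net.add_edge(name_a, name_b, p_value=p, observed=observed)
    return ModuleNetwork(graph=net, alpha=alpha, n_perm=n_perm)
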