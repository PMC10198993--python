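"""Shared fixtures and independent oracles."""

from math import factorial

import networkx as nx
import pytest


def brute_force_maximal_cliques(graph: nx.Graph) -> set[frozenset]:
    """Exhaustive subset enumeration of maximal cliques (graphs <= ~15 nodes).

    Independent of the production path: subsets are encoded as bitmasks and
    checked for completeness against adjacency masks, then for maximality
    against every outside vertex.
    """
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for a, b in graph.edges:
        adj[index[a]] |= 1 << index[b]
        adj[index[b]] |= 1 << index[a]

    def is_clique(mask: int) -> bool:
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if (mask & ~(1 << i)) & ~adj[i]:
                return False
            m &= m - 1
        return True

    cliques = set()
    for mask in range(1, 1 << len(nodes)):
        if not is_clique(mask):
            continue
        maximal = True
        for i in range(len(nodes)):
            if not mask & (1 << i) and (mask & adj[i]) == mask:
                maximal = False
                break
        if maximal:
            cliques.add(
                frozenset(nodes[i] for i in range(len(nodes)) if mask & (1 << i))
            )
    return cliques


def brute_force_mcc(graph: nx.Graph) -> dict:
    """MCC from the brute-force clique enumeration."""
    scores = {v: 0 for v in graph.nodes}
    for clique in brute_force_maximal_cliques(graph):
        for v in clique:
            scores[v] += factorial(len(clique) - 1)
    return scores


@pytest.fixture
def k4_pendant() -> nx.Graph:
    """K4 on a,b,c,d plus a pendant p attached to a."""
    g = nx.complete_graph(["a", "b", "c", "d"])
    g.add_edge("a", "p")
    return g
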