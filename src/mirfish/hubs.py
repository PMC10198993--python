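"""Hub-protein ranking by Maximal Clique Centrality (MCC).

MCC scores a node by summing, over every maximal clique C that contains it,
the factorial (|C| - 1)!.  Nodes sitting in large, or many, maximal cliques
therefore dominate the ranking; it is the hub statistic popularized by the
CytoHubba plugin for prioritizing essential proteins in interactomes.
Edge weights are ignored: cliques are a purely topological notion.

Factorials are taken in exact integer arithmetic — (|C|-1)! exceeds float
precision for cliques of modest size.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Iterable, Sequence

import networkx as nx


@dataclass(frozen=True)
class HubTable:
    """MCC scores plus the deterministic hub ranking."""

    scores: dict[str, int]
    ranked: tuple[str, ...]


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques, each sorted, in sorted overall order.

    Enumeration is Bron–Kerbosch with pivoting (networkx); isolated nodes
    appear as singleton cliques, so every node belongs to at least one clique.
    """
    return sorted(tuple(sorted(c)) for c in nx.find_cliques(graph))


def mcc_scores(graph: nx.Graph) -> HubTable:
    """Maximal Clique Centrality for every node.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.
    An isolated node scores 1: its singleton is its only maximal clique and
    (1-1)! = 1.  Ranking ties are broken by higher degree, then by symbol.
    """
    scores: dict[str, int] = {node: 0 for node in graph.nodes}
    for clique in nx.find_cliques(graph):
        contribution = factorial(len(clique) - 1)
        for node in clique:
            scores[node] += contribution
    ranked = tuple(
        sorted(scores, key=lambda v: (-scores[v], -graph.degree(v), v))
    )
    return HubTable(scores=scores, ranked=ranked)


def top_k(table: HubTable, k: int = 10) -> list[str]:
    """The ``k`` highest-MCC nodes in rank order (all nodes if k > n)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(table.ranked[:k])


def intersect_annotated(hubs: Sequence[str], annotation: Iterable[str]) -> list[str]:
    """Hubs carrying a given annotation, reported in hub-rank order."""
    annotated = set(annotation)
    return [h for h in hubs if h in annotated]
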