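"""Protein–protein interaction network construction and scale-free selection.

A candidate network is grown from a seed protein set by "sphere expansion":
the best-connected non-seed neighbours are added (first sphere), then
optionally their best neighbours (second sphere), mirroring how interaction
databases let a user pad a query set with high-confidence partners.  Each
candidate's degree distribution is then fitted to a power law
``P(k) ~ k^-gamma`` by ordinary least squares on log-log axes, and the
candidate with the highest R² — the most scale-free one — is selected for
downstream hub analysis.

Graphs are undirected :class:`networkx.Graph` objects.  Nodes carry a
``role`` attribute (``"seed"`` or ``"added"``); edges carry a confidence
``score`` in (0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats

from .errors import ConfigError, DegenerateFitError, ParseError

DEFAULT_SCORE_FLOOR = 0.4


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log P(k) against log k over the distinct degrees k >= 1.

    Attributes
    ----------
    gamma : float
        Estimated exponent (minus the fitted slope); positive for
        heavy-tailed networks.
    r_squared : float
        Coefficient of determination of the log-log regression.
    n_points : int
        Number of distinct degree values used in the fit.
    """

    gamma: float
    r_squared: float
    n_points: int


def read_edge_list(path: str | Path, score_floor: float = DEFAULT_SCORE_FLOOR) -> nx.Graph:
    """Read a STRING-style three-column TSV (protein1, protein2, combined_score).

    Scores on STRING's 0–1000 integer scale are auto-detected (any value > 1)
    and normalized by 1000.  Edges with score <= ``score_floor`` are dropped
    (the confidence filter is strict).  Duplicate undirected edges keep the
    maximum score; self-loops are discarded.

    Raises
    ------
    ParseError
        On a malformed row, with its 1-based line number.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                # tolerate space-separated input
                parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"expected 3 columns, got {len(parts)}", line=lineno)
            a, b, raw_score = parts
            if not a or not b:
                raise ParseError("empty protein identifier", line=lineno)
            try:
                score = float(raw_score)
            except ValueError:
                raise ParseError(f"non-numeric score {raw_score!r}", line=lineno) from None
            if score < 0:
                raise ParseError(f"negative score {score}", line=lineno)
            rows.append((a, b, score))

    if any(score > 1 for _, _, score in rows):
        rows = [(a, b, score / 1000.0) for a, b, score in rows]

    graph = nx.Graph()
    for a, b, score in rows:
        if a == b:
            continue
        if score <= score_floor:
            continue
        if graph.has_edge(a, b):
            score = max(score, graph[a][b]["score"])
        graph.add_edge(a, b, score=score)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as a sorted, deterministic three-column TSV."""
    lines = sorted(
        (min(a, b), max(a, b), data["score"]) for a, b, data in graph.edges(data=True)
    )
    with open(path, "w") as fh:
        for a, b, score in lines:
            fh.write(f"{a}\t{b}\t{score:.6g}\n")


def _score_to_set(graph: nx.Graph, node: str, targets: set[str]) -> float:
    return sum(
        graph[node][nbr]["score"] for nbr in graph.neighbors(node) if nbr in targets
    )


def _top_neighbors(graph: nx.Graph, current: set[str], k: int) -> list[str]:
    """Non-member neighbours of ``current``, ranked by summed edge score to it.

    Ties are broken lexicographically by symbol so expansion is deterministic.
    """
    candidates = set()
    for node in current:
        if node in graph:
            candidates.update(n for n in graph.neighbors(node) if n not in current)
    ranked = sorted(candidates, key=lambda n: (-_score_to_set(graph, n, current), n))
    return ranked[:k]


def expand_network(
    interactome: nx.Graph,
    seeds: Iterable[str],
    first_sphere: int,
    second_sphere: int,
) -> nx.Graph:
    """Grow a candidate network around ``seeds`` by two spheres of expansion.

    The first sphere adds the ``first_sphere`` non-seed neighbours with the
    highest summed edge score to the seed set; the second sphere adds the
    ``second_sphere`` best neighbours of the enlarged set.  The result is the
    induced subgraph on the selected nodes.  Seeds missing from the
    interactome are retained as isolated nodes.

    Raises
    ------
    ConfigError
        If a sphere size is negative.
    """
    if first_sphere < 0 or second_sphere < 0:
        raise ConfigError("sphere sizes must be non-negative")
    seed_set = set(seeds)

    selected = set(seed_set)
    selected.update(_top_neighbors(interactome, seed_set, first_sphere))
    if second_sphere > 0:
        selected.update(_top_neighbors(interactome, selected, second_sphere))

    result = nx.Graph()
    for node in selected:
        result.add_node(node, role="seed" if node in seed_set else "added")
    for a, b, data in interactome.subgraph(selected & set(interactome)).edges(data=True):
        result.add_edge(a, b, score=data["score"])
    return result


def fit_power_law(graph: nx.Graph) -> PowerLawFit:
    """Fit P(k) ~ k^-gamma on the graph's degree distribution.

    P(k) is the fraction of *all* nodes having degree k; degree-0 nodes count
    in the denominator but contribute no fit point (log 0 is undefined).  The
    regression is ordinary least squares of log P(k) on log k over the
    distinct observed degrees k >= 1, the convention used by network-analysis
    GUIs when they report a gamma/R² table.

    Raises
    ------
    DegenerateFitError
        With fewer than two distinct positive degrees.
    """
    n = graph.number_of_nodes()
    counts: dict[int, int] = {}
    for _, degree in graph.degree():
        if degree >= 1:
            counts[degree] = counts.get(degree, 0) + 1
    if len(counts) < 2:
        raise DegenerateFitError(
            f"need >= 2 distinct positive degrees, got {len(counts)}"
        )
    ks = sorted(counts)
    log_k = [math.log(k) for k in ks]
    log_p = [math.log(counts[k] / n) for k in ks]
    fit = stats.linregress(log_k, log_p)
    return PowerLawFit(
        gamma=-fit.slope, r_squared=fit.rvalue**2, n_points=len(ks)
    )


def select_network(
    candidates: Sequence[tuple[tuple, nx.Graph]],
) -> tuple[tuple, nx.Graph, PowerLawFit, list[dict]]:
    """Pick the most scale-free candidate network (highest fit R²).

    Parameters
    ----------
    candidates : sequence of (settings, graph)
        ``settings`` is any comparable tuple, typically
        ``(first_sphere, second_sphere)``.

    Returns
    -------
    (settings, graph, fit, table)
        The winner plus a full fit table (one dict per candidate; candidates
        whose fit is degenerate are listed with ``fit: None``).

    Ties on R² are broken by smaller node count, then by the lexicographically
    smallest settings, so selection is independent of input order.

    Raises
    ------
    DegenerateFitError
        If no candidate admits a fit.
    """
    table: list[dict] = []
    fitted: list[tuple[tuple, nx.Graph, PowerLawFit]] = []
    for settings, graph in candidates:
        entry = {
            "settings": settings,
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
        }
        try:
            fit = fit_power_law(graph)
        except DegenerateFitError:
            entry.update(gamma=None, r_squared=None)
        else:
            entry.update(gamma=fit.gamma, r_squared=fit.r_squared)
            fitted.append((settings, graph, fit))
        table.append(entry)
    if not fitted:
        raise DegenerateFitError("no candidate network admits a power-law fit")
    best = min(
        fitted,
        key=lambda item: (-item[2].r_squared, item[1].number_of_nodes(), item[0]),
    )
    return (*best, table)
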