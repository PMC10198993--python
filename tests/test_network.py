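"""Edge-list parsing, sphere expansion, and the scale-free fit/selection."""

import math

import networkx as nx
import pytest

from mirfish.errors import ConfigError, DegenerateFitError, ParseError
from mirfish.fixtures import fixture_path, seed_symbols
from mirfish.network import (
    expand_network,
    fit_power_law,
    read_edge_list,
    select_network,
)


class TestReadEdgeList:
    def test_reads_edges_above_floor(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t0.5\nB\tC\t0.9\nC\tD\t0.41\n")
        graph = read_edge_list(path)
        assert graph.number_of_edges() == 3

    def test_score_at_floor_dropped(self, tmp_path):
        # "more than 0.4" is strict: 0.4 itself fails
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t0.4\nB\tC\t0.5\n")
        graph = read_edge_list(path)
        assert not graph.has_edge("A", "B")
        assert graph.has_edge("B", "C")

    def test_integer_scale_normalized(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t700\n")
        graph = read_edge_list(path)
        assert graph["A"]["B"]["score"] == pytest.approx(0.7)

    def test_duplicate_edge_keeps_max_score(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t0.5\nB\tA\t0.8\n")
        graph = read_edge_list(path)
        assert graph.number_of_edges() == 1
        assert graph["A"]["B"]["score"] == 0.8

    def test_self_loop_dropped(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tA\t0.9\nA\tB\t0.9\n")
        assert read_edge_list(path).number_of_edges() == 1

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t0.5\nA\tB\n")
        with pytest.raises(ParseError, match="line 2"):
            read_edge_list(path)

    def test_non_numeric_score_reports_line_number(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\thigh\n")
        with pytest.raises(ParseError, match="line 1"):
            read_edge_list(path)


def _weighted(edges):
    g = nx.Graph()
    for a, b, s in edges:
        g.add_edge(a, b, score=s)
    return g


class TestExpandNetwork:
    def test_zero_spheres_is_seed_induced_subgraph(self):
        g = _weighted([("A", "B", 0.9), ("B", "X", 0.9)])
        net = expand_network(g, {"A", "B"}, 0, 0)
        assert set(net.nodes) == {"A", "B"}
        assert net.has_edge("A", "B")

    def test_second_sphere_zero_adds_no_distance_two_nodes(self):
        g = _weighted([("A", "X", 0.9), ("X", "Y", 0.9)])
        net = expand_network(g, {"A"}, 1, 0)
        assert set(net.nodes) == {"A", "X"}

    def test_missing_seed_kept_isolated(self):
        g = _weighted([("A", "B", 0.9)])
        net = expand_network(g, {"A", "GHOST"}, 0, 0)
        assert net.nodes["GHOST"]["role"] == "seed"
        assert net.degree("GHOST") == 0

    def test_neighbor_ranking_by_summed_score(self):
        g = _weighted(
            [("A", "X", 0.5), ("B", "X", 0.5), ("A", "Y", 0.6)]
        )
        net = expand_network(g, {"A", "B"}, 1, 0)
        # X: 1.0 summed beats Y: 0.6
        assert "X" in net and "Y" not in net

    def test_monotone_in_first_sphere(self):
        g = _weighted(
            [(f"S{i}", f"N{j}", 0.5 + 0.01 * j) for i in range(3) for j in range(8)]
        )
        seeds = {"S0", "S1", "S2"}
        previous: set = set()
        for first in range(0, 9, 2):
            nodes = set(expand_network(g, seeds, first, 0).nodes)
            assert previous <= nodes
            previous = nodes

    def test_negative_sphere_rejected(self):
        with pytest.raises(ConfigError):
            expand_network(nx.Graph(), set(), -1, 0)

    def test_fixture_interactome_reproduces_published_network_size(self):
        """25 seeds, first sphere 10, no second sphere: 35 proteins and 110
        interactions, the published network summary."""
        graph = read_edge_list(fixture_path("interactome"))
        net = expand_network(graph, seed_symbols(), 10, 0)
        assert net.number_of_nodes() == 35
        assert net.number_of_edges() == 110
        roles = {d["role"] for _, d in net.nodes(data=True)}
        assert roles == {"seed", "added"}


def _star(leaves):
    g = nx.Graph()
    for i in range(leaves):
        g.add_edge("hub", f"leaf{i}")
    return g


def _from_degree_histogram(hist):
    """Assemble a graph with an exact {degree: count} histogram from disjoint
    stars and edges (valid for histograms with enough degree-1 nodes)."""
    g = nx.Graph()
    n1 = hist.get(1, 0)
    used = 0
    for k in sorted(d for d in hist if d > 1):
        for i in range(hist[k]):
            center = f"c{k}_{i}"
            for j in range(k):
                g.add_edge(center, f"l{k}_{i}_{j}")
                used += 1
    assert used <= n1
    remaining = n1 - used
    assert remaining % 2 == 0
    for i in range(remaining // 2):
        g.add_edge(f"p{i}a", f"p{i}b")
    return g


class TestFitPowerLaw:
    def test_star_has_unit_exponent_and_perfect_fit(self):
        # two points: (log 1, log 5/6) and (log 5, log 1/6); slope -1 by hand
        fit = fit_power_law(_star(5))
        assert fit.gamma == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.n_points == 2

    @pytest.mark.parametrize(
        "hist, gamma",
        [
            ({1: 16, 2: 4, 4: 1}, 2.0),  # counts 16/4/1 at k = 1/2/4
            ({1: 8, 2: 1}, 3.0),
            ({1: 27, 3: 1}, 3.0),
        ],
    )
    def test_exact_power_law_recovered_exactly(self, hist, gamma):
        graph = _from_degree_histogram(hist)
        # sanity: assembled graph has the intended histogram
        observed = {}
        for _, d in graph.degree():
            observed[d] = observed.get(d, 0) + 1
        assert observed == hist
        fit = fit_power_law(graph)
        assert fit.gamma == pytest.approx(gamma, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_single_degree_graph_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_power_law(nx.complete_graph(5))

    def test_isolated_nodes_count_in_denominator_but_not_as_points(self):
        g = _star(5)
        g.add_node("isolated")
        fit = fit_power_law(g)
        assert fit.n_points == 2
        # P(5) = 1/7 now; slope = log(1/5)/log 5 = -1 still
        assert fit.gamma == pytest.approx(1.0, abs=1e-9)


class TestSelectNetwork:
    def _candidates(self):
        return [
            ((1,), _star(3)),          # r2 = 1 (two points)
            ((2,), nx.path_graph(6)),  # r2 < 1
        ]

    def test_single_candidate_selected(self):
        settings, graph, fit, table = select_network([((0,), _star(4))])
        assert settings == (0,)
        assert len(table) == 1

    def test_highest_r_squared_wins(self):
        settings, _, fit, table = select_network(self._candidates())
        assert settings == (1,)
        assert fit.r_squared == pytest.approx(1.0)
        assert {row["settings"] for row in table} == {(1,), (2,)}

    def test_tie_broken_by_fewer_nodes(self):
        small, large = _star(2), _star(3)  # both fit r2 = 1 exactly
        settings, graph, _, _ = select_network([((9,), large), ((5,), small)])
        assert settings == (5,)
        assert graph.number_of_nodes() == 3

    def test_selection_is_permutation_invariant(self):
        candidates = self._candidates() + [((3,), _star(5))]
        winner = select_network(candidates)[0]
        assert select_network(candidates[::-1])[0] == winner

    def test_all_degenerate_rejected(self):
        with pytest.raises(DegenerateFitError):
            select_network([((0,), nx.complete_graph(4))])
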