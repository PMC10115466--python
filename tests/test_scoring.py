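"""Centrality contracts and IIS scoring against first-principles oracles."""

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from brifin.network import CellNetwork
from brifin.scoring import (
    ScoringError,
    betweenness,
    compute_iis,
    normalize_iis,
    pagerank,
    pruned_distance_graphs,
    top_contributors,
)

from conftest import random_cell_network


def net(edges, contacts=(), extra=()):
    proteins = {u for e in edges for u in e} | set(contacts) | set(extra)
    return CellNetwork("c", proteins, set(edges), set(contacts))


# ---------------------------------------------------------------------------
# PageRank


class TestPageRank:
    def test_single_node(self):
        t = pagerank(net([], extra=["A"]))
        assert t.scores == {"A": pytest.approx(1.0)}

    def test_triangle_uniform(self):
        t = pagerank(net([("A", "B"), ("B", "C"), ("A", "C")]))
        for s in t.scores.values():
            assert s == pytest.approx(1 / 3, abs=1e-9)

    def test_scores_sum_to_one(self, rng):
        for _ in range(5):
            n = random_cell_network(rng)
            assert sum(pagerank(n).scores.values()) == pytest.approx(1.0, abs=1e-6)

    def test_star_center_dominates_and_matches_oracle(self):
        """Converged star scores match networkx's independent implementation."""
        star = net([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        mine = pagerank(star, epsilon=1e-13).scores
        ref = nx.pagerank(star.graph(), alpha=0.85, tol=1e-15, max_iter=100000)
        assert all(mine["hub"] > mine[l] for l in ("l1", "l2", "l3"))
        for u in mine:
            assert mine[u] == pytest.approx(ref[u], abs=1e-9)

    def test_matches_independent_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            n = random_cell_network(rng, n_max=25)
            mine = pagerank(n, epsilon=1e-13).scores
            ref = nx.pagerank(n.graph(), alpha=0.85, tol=1e-15, max_iter=100000)
            for u in mine:
                assert mine[u] == pytest.approx(ref[u], abs=1e-8)

    def test_label_permutation_equivariance(self, rng):
        n = random_cell_network(rng, n_max=15)
        perm = {u: f"q{i}" for i, u in enumerate(sorted(n.proteins))}
        permuted = CellNetwork(
            "c",
            {perm[u] for u in n.proteins},
            {(perm[u], perm[v]) for u, v in n.edges},
        )
        base = pagerank(n, epsilon=1e-12).scores
        relabeled = pagerank(permuted, epsilon=1e-12).scores
        for u, s in base.items():
            assert relabeled[perm[u]] == pytest.approx(s, abs=1e-12)

    def test_bad_parameters_rejected(self):
        g = net([("A", "B")])
        with pytest.raises(ScoringError):
            pagerank(g, damping=1.5)
        with pytest.raises(ScoringError):
            pagerank(g, epsilon=0.0)


# ---------------------------------------------------------------------------
# Betweenness


def betweenness_oracle(g: nx.Graph) -> dict:
    """Geodesic enumeration: fraction of shortest s-t paths through each node."""
    bc = dict.fromkeys(g, 0.0)
    for s, t in combinations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


class TestBetweenness:
    def test_path_middle_node(self):
        t = betweenness(net([("A", "B"), ("B", "C")]))
        assert t.scores == {"A": 0.0, "B": pytest.approx(1.0), "C": 0.0}

    def test_complete_graph_all_zero(self):
        k4 = net([(a, b) for a, b in combinations("ABCD", 2)])
        assert all(v == 0.0 for v in betweenness(k4).scores.values())

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            n = random_cell_network(rng, n_max=8)
            mine = betweenness(n).scores
            ref = betweenness_oracle(n.graph())
            for u in mine:
                assert mine[u] == pytest.approx(ref[u], abs=1e-9)


# ---------------------------------------------------------------------------
# Pruned graphs and IIS


class TestPrunedGraphs:
    def test_definition(self):
        n = net([("c1", "n1"), ("n1", "c2"), ("c1", "c2")], contacts=["c1", "c2"])
        g1, g2 = pruned_distance_graphs(n)
        assert set(map(tuple, map(sorted, g1.edges))) == {("c1", "n1"), ("c2", "n1")}
        assert set(map(tuple, map(sorted, g2.edges))) == {("c1", "c2")}

    def test_no_contact_contact_edges_is_identity(self):
        n = net([("c1", "n1"), ("n1", "n2")], contacts=["c1"])
        g1, _ = pruned_distance_graphs(n)
        assert g1.number_of_edges() == 2

    def test_all_contacts(self):
        n = net([("c1", "c2"), ("c2", "c3")], contacts=["c1", "c2", "c3"])
        g1, g2 = pruned_distance_graphs(n)
        assert g1.number_of_edges() == 0
        assert g2.number_of_edges() == 2


def bfs_distances(nodes, edges, source):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def iis_oracle(network: CellNetwork, scores: dict) -> dict:
    """First-principles IIS: rebuild both pruned edge sets, BFS by hand."""
    contacts = network.contacts
    e1 = {e for e in network.edges if not (e[0] in contacts and e[1] in contacts)}
    e2 = {e for e in network.edges if e[0] in contacts and e[1] in contacts}
    out = {}
    for i in contacts:
        d1 = bfs_distances(network.proteins, e1, i)
        d2 = bfs_distances(contacts, e2, i)
        total = sum(
            scores[j] / d for j, d in d1.items() if j not in contacts and d > 0
        )
        total += sum(scores[k] / d for k, d in d2.items() if k != i and d > 0)
        out[i] = total
    return out


class TestComputeIIS:
    def test_isolated_contact_scores_zero(self):
        n = net([("a", "b")], contacts=["cL"], extra=["cL"])
        cent = pagerank(n)
        assert compute_iis(n, cent).raw["cL"] == 0.0

    def test_triangle_fixture_hand_value(self):
        """IIS(c1) = PR(n1)/1 + PR(c2)/1 on the contact triangle."""
        n = net([("c1", "n1"), ("n1", "c2"), ("c1", "c2")], contacts=["c1", "c2"])
        cent = pagerank(n, epsilon=1e-12)
        table = compute_iis(n, cent)
        assert table.raw["c1"] == pytest.approx(
            cent.scores["n1"] + cent.scores["c2"], abs=1e-12
        )

    def test_contact_unreachable_through_non_contacts(self):
        """Term 2 is 0 when the only contact-contact path runs via a non-contact."""
        n = net([("c1", "n1"), ("n1", "c2")], contacts=["c1", "c2"])
        cent = pagerank(n, epsilon=1e-12)
        table = compute_iis(n, cent)
        assert table.raw["c1"] == pytest.approx(cent.scores["n1"], abs=1e-12)
        assert "c2" not in table.contributions["c1"]

    def test_raw_equals_sum_of_contributions(self, rng):
        n = random_cell_network(rng)
        table = compute_iis(n, pagerank(n))
        for i, r in table.raw.items():
            assert r == pytest.approx(sum(table.contributions[i].values()), abs=1e-9)

    def test_matches_first_principles_oracle(self, rng):
        for _ in range(50):
            n = random_cell_network(rng, n_max=40)
            cent = pagerank(n)
            mine = compute_iis(n, cent).raw
            ref = iis_oracle(n, cent.scores)
            for i in n.contacts:
                assert mine[i] == pytest.approx(ref[i], abs=1e-9)

    def test_disconnected_component_does_not_change_scores(self):
        base = net([("c1", "n1"), ("n1", "c2")], contacts=["c1", "c2"])
        cent = pagerank(base, epsilon=1e-12)
        bigger = net(
            [("c1", "n1"), ("n1", "c2"), ("z1", "z2")], contacts=["c1", "c2"]
        )
        # reuse the small network's centrality so only distances could differ
        t1 = compute_iis(base, cent)
        t2 = compute_iis(bigger, cent)
        for i in ("c1", "c2"):
            assert t1.raw[i] == pytest.approx(t2.raw[i], abs=1e-12)

    def test_missing_centrality_rejected(self):
        n = net([("c1", "n1")], contacts=["c1"])
        from brifin.scoring import CentralityTable

        with pytest.raises(ScoringError):
            compute_iis(n, CentralityTable("c", "pagerank", {"n1": 1.0}))


class TestNormalizeAndContributors:
    def test_max_scaling(self):
        n = net([("c1", "n1"), ("n1", "c2"), ("c1", "c2")], contacts=["c1", "c2"])
        table = normalize_iis(compute_iis(n, pagerank(n)))
        assert max(table.normalized.values()) == pytest.approx(1.0)
        ordered_raw = sorted(table.raw, key=table.raw.get)
        ordered_norm = sorted(table.normalized, key=table.normalized.get)
        assert ordered_raw == ordered_norm

    def test_zero_score_floored(self):
        n = net([("c1", "n1")], contacts=["c1", "cL"], extra=["cL"])
        table = normalize_iis(compute_iis(n, pagerank(n)), floor=1e-9)
        assert table.normalized["cL"] == 1e-9

    def test_all_zero_rejected(self):
        n = net([("a", "b")], contacts=["cL"], extra=["cL"])
        with pytest.raises(ScoringError):
            normalize_iis(compute_iis(n, pagerank(n)))

    def test_single_contact_self_normalizes(self):
        n = net([("c1", "n1")], contacts=["c1"])
        table = normalize_iis(compute_iis(n, pagerank(n)))
        assert table.normalized["c1"] == pytest.approx(1.0)

    def test_top_contributors_sorted_and_truncated(self, rng):
        n = random_cell_network(rng, n_max=30)
        table = compute_iis(n, pagerank(n))
        i = max(table.raw, key=table.raw.get)
        top = top_contributors(table, i, k=5)
        assert len(top) <= 5
        values = [v for _, v in top]
        assert values == sorted(values, reverse=True)

    def test_top_contributors_tie_order_lexicographic(self):
        # two leaves at equal distance and equal centrality tie on contribution
        n = net([("c", "b"), ("c", "a")], contacts=["c"])
        table = compute_iis(n, pagerank(n, epsilon=1e-12))
        names = [j for j, _ in top_contributors(table, "c")]
        assert names == sorted(names, key=lambda x: (-table.contributions["c"][x], x))

    def test_unknown_protein_rejected(self):
        n = net([("c1", "n1")], contacts=["c1"])
        with pytest.raises(ScoringError):
            top_contributors(compute_iis(n, pagerank(n)), "nope")
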