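"""Shared fixtures: random networks and random bridge problems."""

from __future__ import annotations

import numpy as np
import pytest

from brifin.ilp import BridgeProblem, coverage_relation
from brifin.network import CellNetwork, InterNetwork


def random_cell_network(
    rng: np.random.Generator,
    n_max: int = 40,
    label: str = "cell1",
    contact_frac: float = 0.3,
) -> CellNetwork:
    """A random simple undirected graph with a random contact subset."""
    n = int(rng.integers(4, n_max + 1))
    names = [f"p{i}" for i in range(n)]
    p_edge = min(1.0, 2.5 / n + 0.05)
    edges = {
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p_edge
    }
    n_contacts = max(1, int(round(contact_frac * n)))
    contacts = {names[i] for i in rng.choice(n, size=n_contacts, replace=False)}
    return CellNetwork(label, set(names), edges, contacts)


def random_problem(
    rng: np.random.Generator, max_pairs: int = 12
) -> BridgeProblem:
    """A random bipartite topology with uniform random pair costs."""
    n1 = int(rng.integers(2, 6))
    n2 = int(rng.integers(2, 6))
    all_pairs = [(f"u{i}", f"v{j}") for i in range(n1) for j in range(n2)]
    k = int(rng.integers(1, min(max_pairs, len(all_pairs)) + 1))
    idx = rng.choice(len(all_pairs), size=k, replace=False)
    inter = InterNetwork("cell1", "cell2", {all_pairs[i] for i in idx})
    pairs = sorted(inter.edges)
    pidx = {p: i for i, p in enumerate(pairs)}
    rel = coverage_relation(inter)
    cover = [frozenset(pidx[e] for e in rel[p]) for p in pairs]
    cost = {p: float(rng.uniform(0.2, 5.0)) for p in pairs}
    return BridgeProblem(pairs, cost, cover)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
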