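"""Centrality and intracellular importance scores (IIS) for contact proteins.

Each contact protein i of a cell receives

    IIS_i = sum_{j in NC_i} PR_j / d_ij  +  sum_{k in C_i, k != i} PR_k / d_ik

where PR is a centrality score (PageRank by default, betweenness as an
alternative), NC_i are the cell's non-contact proteins and C_i its other
contact proteins. The two distance terms are measured on two different pruned
graphs: the first on the network with all contact-contact edges removed, the
second on the induced subgraph of the contact proteins only. Distances are
unit-weight BFS hop counts; unreachable proteins contribute nothing. This
pruning sharpens score differences that the small-world character of PPI
networks would otherwise flatten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .network import CellNetwork

__all__ = [
    "CentralityTable",
    "IISTable",
    "ScoringError",
    "pagerank",
    "betweenness",
    "pruned_distance_graphs",
    "compute_iis",
    "normalize_iis",
    "top_contributors",
]

DEFAULT_DAMPING = 0.85
DEFAULT_EPSILON = 1e-3
DEFAULT_FLOOR = 1e-9


class ScoringError(ValueError):
    """Raised for missing scores, non-convergence, or degenerate inputs."""


@dataclass
class CentralityTable:
    """Per-protein centrality scores for one cell.

    ``metric`` is ``"pagerank"`` (scores sum to 1) or ``"betweenness"``
    (unnormalized Brandes values); either can stand in for PR in the IIS.
    """

    cell_label: str
    metric: str
    scores: dict[str, float]


@dataclass
class IISTable:
    """Raw and normalized IIS per contact protein, with additive contributions.

    ``contributions[i]`` maps each contributing protein j to its additive term
    PR_j / d_ij, so ``raw[i]`` equals the sum of ``contributions[i].values()``.
    Normalized scores are raw scores divided by the per-cell maximum, floored
    at a small positive value so every contact protein keeps a finite pair
    cost downstream.
    """

    cell_label: str
    metric: str
    raw: dict[str, float]
    contributions: dict[str, dict[str, float]]
    normalized: dict[str, float] = field(default_factory=dict)
    floor: float = DEFAULT_FLOOR


def pagerank(
    network: CellNetwork,
    damping: float = DEFAULT_DAMPING,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = 1000,
) -> CentralityTable:
    """PageRank by power iteration on the undirected graph.

    Each undirected edge is treated as a pair of directed edges. Starting from
    the uniform vector, sweeps continue until the total L1 change across nodes
    drops below ``epsilon`` (the classic network-tool default semantics, with
    damping 0.85 and epsilon 0.001). Mass on isolated (dangling) nodes is
    redistributed uniformly. Scores are renormalized to sum to 1.
    """
    if not network.proteins:
        raise ScoringError(f"cell {network.cell_label!r}: empty network")
    if not 0.0 < damping < 1.0:
        raise ScoringError(f"damping must be in (0, 1), got {damping}")
    if epsilon <= 0:
        raise ScoringError(f"epsilon must be positive, got {epsilon}")

    nodes = sorted(network.proteins)
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in network.edges:
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])
    degree = [len(a) for a in adj]

    x = [1.0 / n] * n
    base = (1.0 - damping) / n
    for _ in range(max_iter):
        dangling = sum(x[i] for i in range(n) if degree[i] == 0)
        new = [base + damping * dangling / n] * n
        for i in range(n):
            if degree[i]:
                share = damping * x[i] / degree[i]
                for j in adj[i]:
                    new[j] += share
        delta = sum(abs(new[i] - x[i]) for i in range(n))
        x = new
        if delta < epsilon:
            break
    else:
        raise ScoringError(
            f"cell {network.cell_label!r}: PageRank did not converge in {max_iter} sweeps"
        )
    total = sum(x)
    scores = {u: x[index[u]] / total for u in nodes}
    return CentralityTable(network.cell_label, "pagerank", scores)


def betweenness(network: CellNetwork) -> CentralityTable:
    """Unnormalized shortest-path betweenness (each unordered pair counted once)."""
    if not network.proteins:
        raise ScoringError(f"cell {network.cell_label!r}: empty network")
    scores = nx.betweenness_centrality(network.graph(), normalized=False)
    return CentralityTable(network.cell_label, "betweenness", dict(scores))


def pruned_distance_graphs(network: CellNetwork) -> tuple[nx.Graph, nx.Graph]:
    """The two distance graphs used by the IIS.

    Returns ``(g_noncontact, g_contact)`` where the first keeps all nodes but
    removes every contact-contact edge, and the second is the induced subgraph
    on the contact proteins only.
    """
    contacts = network.contacts
    g1 = nx.Graph()
    g1.add_nodes_from(network.proteins)
    g1.add_edges_from(
        (u, v) for u, v in network.edges if not (u in contacts and v in contacts)
    )
    g2 = nx.Graph()
    g2.add_nodes_from(contacts)
    g2.add_edges_from((u, v) for u, v in network.edges if u in contacts and v in contacts)
    return g1, g2


def compute_iis(network: CellNetwork, centrality: CentralityTable) -> IISTable:
    """Score every contact protein from BFS distances on the two pruned graphs.

    Term 1 sums centrality/distance over non-contact proteins reachable in the
    contact-edge-pruned graph; term 2 over other contact proteins reachable in
    the contact-only graph. Unreachable proteins contribute 0. A contact
    protein with no intracellular edges scores 0 (both sums empty).
    """
    missing = network.contacts - centrality.scores.keys()
    if missing:
        raise ScoringError(
            f"cell {network.cell_label!r}: contact protein(s) absent from the "
            f"centrality table: {sorted(missing)[:5]}"
        )
    g1, g2 = pruned_distance_graphs(network)
    non_contacts = network.non_contacts
    raw: dict[str, float] = {}
    contributions: dict[str, dict[str, float]] = {}
    for i in network.contacts:
        contrib: dict[str, float] = {}
        for j, d in nx.single_source_shortest_path_length(g1, i).items():
            if j in non_contacts and d > 0:
                contrib[j] = centrality.scores[j] / d
        for k, d in nx.single_source_shortest_path_length(g2, i).items():
            if k != i and d > 0:
                contrib[k] = centrality.scores[k] / d
        raw[i] = sum(contrib.values())
        contributions[i] = contrib
    return IISTable(
        cell_label=network.cell_label,
        metric=centrality.metric,
        raw=raw,
        contributions=contributions,
    )


def normalize_iis(table: IISTable, floor: float = DEFAULT_FLOOR) -> IISTable:
    """Divide by the per-cell maximum raw score, flooring at a small positive value.

    Max-scaling (rather than min-max) keeps every score strictly positive so
    that the downstream pair cost 1/(sum of scores) stays finite, while
    preserving the score ordering.
    """
    if not table.raw:
        raise ScoringError(f"cell {table.cell_label!r}: no contact proteins to normalize")
    top = max(table.raw.values())
    if top <= 0:
        raise ScoringError(
            f"cell {table.cell_label!r}: all raw IIS values are zero; nothing to rank"
        )
    table.normalized = {i: max(r / top, floor) for i, r in table.raw.items()}
    table.floor = floor
    return table


def top_contributors(
    table: IISTable, protein: str, k: int = 20
) -> list[tuple[str, float]]:
    """The ``k`` largest additive IIS terms for one contact protein.

    Sorted by contribution descending, ties broken lexicographically by
    contributor identifier; useful for asking which intracellular proteins
    drive a contact protein's score.
    """
    if protein not in table.contributions:
        raise ScoringError(
            f"cell {table.cell_label!r}: unknown contact protein {protein!r}"
        )
    items = sorted(table.contributions[protein].items(), key=lambda kv: (-kv[1], kv[0]))
    return items[:k]
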