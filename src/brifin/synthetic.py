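"""Synthetic two-cell interactomes with controllable structure.

Real inputs to a bridge analysis are two intracellular PPI networks, a contact
subset per cell, and a sparse bipartite intercellular network. The generator
emulates that structure at desk scale: heavy-tailed intracellular graphs grown
by preferential attachment (PPI networks are dominated by hubs), a designated
contact pool per cell, and intercellular edges sampled over the contact pools.

A configurable number of *planted bridge* contacts per cell receive boosted
wiring — extra intracellular edges to the highest-degree proteins (raising
their centrality-over-distance score) and a quota of intercellular edges
(raising their coverage degree). They are the operational ground truth for
recovery experiments; their identities are returned alongside the networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import CellNetwork, CellProteinRef, InterNetwork, write_edge_list

__all__ = ["SyntheticSpec", "SyntheticInstance", "generate", "write_inputs", "worked_fixture"]


@dataclass
class SyntheticSpec:
    """Generation parameters for a two-cell synthetic instance.

    Defaults describe a desk-scale interactome: a few hundred proteins per
    cell at mean degree ~6 (sparse, hub-dominated), 15% of proteins in the
    contact pool, a few dozen intercellular edges, and two planted bridge
    proteins per cell.
    """

    n1: int = 300
    n2: int = 250
    m1: int = 900
    m2: int = 750
    contact_frac1: float = 0.15
    contact_frac2: float = 0.15
    inter_edges: int = 60
    topology: str = "preferential_attachment"
    planted_bridge_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        for label, n, m in (("cell 1", self.n1, self.m1), ("cell 2", self.n2, self.m2)):
            if n < 4:
                raise ValueError(f"{label}: need at least 4 proteins, got {n}")
            if m > n * (n - 1) // 2:
                raise ValueError(f"{label}: {m} edges exceed simple-graph capacity")
        for label, frac, n in (
            ("cell 1", self.contact_frac1, self.n1),
            ("cell 2", self.contact_frac2, self.n2),
        ):
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"{label}: contact fraction must be in (0, 1]")
            if int(round(frac * n)) < 1:
                raise ValueError(f"{label}: contact pool is empty")
        pool1 = max(1, int(round(self.contact_frac1 * self.n1)))
        pool2 = max(1, int(round(self.contact_frac2 * self.n2)))
        if self.inter_edges < 1 or self.inter_edges > pool1 * pool2:
            raise ValueError(
                f"inter_edges must be in [1, {pool1 * pool2}], got {self.inter_edges}"
            )
        if self.topology not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 <= self.planted_bridge_count <= min(pool1, pool2):
            raise ValueError("planted_bridge_count exceeds a contact pool")


@dataclass
class SyntheticInstance:
    net1: CellNetwork
    net2: CellNetwork
    inter: InterNetwork
    planted: set[CellProteinRef] = field(default_factory=set)


def _grow_cell(
    label: str,
    prefix: str,
    n: int,
    m: int,
    contact_frac: float,
    n_planted: int,
    topology: str,
    rng: np.random.Generator,
) -> tuple[CellNetwork, list[str], list[str]]:
    """One cell: exact edge count, contact pool, planted contacts boosted."""
    names = [f"{prefix}{i:04d}" for i in range(n)]
    pool_size = max(1, int(round(contact_frac * n)))
    pool_idx = rng.choice(n, size=pool_size, replace=False)
    pool = [names[i] for i in sorted(pool_idx)]
    planted = (
        [str(p) for p in rng.choice(pool, size=n_planted, replace=False)]
        if n_planted
        else []
    )

    edges: set[tuple[int, int]] = set()
    degree = np.zeros(n, dtype=float)

    def add(a: int, b: int) -> bool:
        if a == b:
            return False
        e = (a, b) if a < b else (b, a)
        if e in edges:
            return False
        edges.add(e)
        degree[a] += 1
        degree[b] += 1
        return True

    if topology == "erdos_renyi":
        while len(edges) < m:
            a, b = rng.integers(0, n, size=2)
            add(int(a), int(b))
    else:
        # spanning tree grown preferentially: early nodes become hubs
        order = rng.permutation(n)
        for t in range(1, n):
            if len(edges) >= m:
                break
            existing = order[:t]
            w = degree[existing] + 1.0
            target = existing[rng.choice(t, p=w / w.sum())]
            add(int(order[t]), int(target))
        # planted contacts wired to the current top-degree proteins
        planted_set = set(planted)
        boost = max(5, n // 20)
        name_to_idx = {u: i for i, u in enumerate(names)}
        for p in planted:
            pi = name_to_idx[p]
            hubs = np.argsort(-degree)
            wired = 0
            for h in hubs:
                if len(edges) >= m or wired >= boost:
                    break
                if names[int(h)] not in planted_set and add(pi, int(h)):
                    wired += 1
        # remaining edges preferential on both endpoints
        while len(edges) < m:
            w = degree + 1.0
            p = w / w.sum()
            a = int(rng.choice(n, p=p))
            b = int(rng.choice(n, p=p))
            add(a, b)

    named_edges = {(names[a], names[b]) for a, b in edges}
    net = CellNetwork(cell_label=label, proteins=set(names), edges=named_edges)
    return net, pool, planted


def generate(spec: SyntheticSpec) -> SyntheticInstance:
    """Generate a reproducible two-cell instance with planted ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    net1, pool1, planted1 = _grow_cell(
        "cell1", "A", spec.n1, spec.m1, spec.contact_frac1,
        spec.planted_bridge_count, spec.topology, rng,
    )
    net2, pool2, planted2 = _grow_cell(
        "cell2", "B", spec.n2, spec.m2, spec.contact_frac2,
        spec.planted_bridge_count, spec.topology, rng,
    )

    inter: set[tuple[str, str]] = set()
    quota = max(1, int(round(0.15 * spec.inter_edges)))
    # planted contacts receive a quota of intercellular edges each
    for p in planted1:
        partners = [str(q) for q in rng.permutation(pool2)]
        got = 0
        for q in partners:
            if got >= quota or len(inter) >= spec.inter_edges:
                break
            if (p, q) not in inter:
                inter.add((p, q))
                got += 1
    for q in planted2:
        partners = [str(p) for p in rng.permutation(pool1)]
        got = 0
        for p in partners:
            if got >= quota or len(inter) >= spec.inter_edges:
                break
            if (p, q) not in inter:
                inter.add((p, q))
                got += 1
    while len(inter) < spec.inter_edges:
        p = str(rng.choice(pool1))
        q = str(rng.choice(pool2))
        inter.add((p, q))

    contacts1 = {u for u, _ in inter}
    contacts2 = {v for _, v in inter}
    net1 = CellNetwork(net1.cell_label, net1.proteins, net1.edges, contacts1)
    net2 = CellNetwork(net2.cell_label, net2.proteins, net2.edges, contacts2)
    planted = {CellProteinRef("cell1", p) for p in planted1 if p in contacts1}
    planted |= {CellProteinRef("cell2", q) for q in planted2 if q in contacts2}
    return SyntheticInstance(
        net1=net1,
        net2=net2,
        inter=InterNetwork("cell1", "cell2", inter),
        planted=planted,
    )


def write_inputs(instance: SyntheticInstance, outdir: str | Path) -> dict[str, Path]:
    """Write the instance in the same TSV formats the readers consume.

    Produces the two edge lists, two proteome lists, the ligand-receptor
    table (one row per intercellular edge, plus a few decoy rows that match
    neither proteome), and the planted ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cell1_edges": outdir / "cell1_edges.tsv",
        "cell2_edges": outdir / "cell2_edges.tsv",
        "cell1_proteome": outdir / "cell1_proteome.txt",
        "cell2_proteome": outdir / "cell2_proteome.txt",
        "lr_pairs": outdir / "lr_pairs.tsv",
        "ground_truth": outdir / "planted_bridges.tsv",
    }
    write_edge_list(instance.net1, paths["cell1_edges"])
    write_edge_list(instance.net2, paths["cell2_edges"])
    for key, net in (("cell1_proteome", instance.net1), ("cell2_proteome", instance.net2)):
        with open(paths[key], "w", encoding="utf-8") as fh:
            for p in sorted(net.proteins):
                fh.write(p + "\n")
    with open(paths["lr_pairs"], "w", encoding="utf-8") as fh:
        fh.write("#partner_a\tpartner_b\n")
        for u, v in sorted(instance.inter.edges):
            fh.write(f"{u}\t{v}\n")
        for i in range(3):  # decoys absent from both proteomes
            fh.write(f"DECOYL{i}\tDECOYR{i}\n")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write("#cell\tprotein\n")
        for ref in sorted(instance.planted):
            fh.write(f"{ref.cell_label}\t{ref.protein_id}\n")
    return paths


# ---------------------------------------------------------------------------
# Hand-built worked fixtures.


def _cell(label: str, edges: set[tuple[str, str]], contacts: set[str],
          extra_proteins: set[str] = frozenset()) -> CellNetwork:
    proteins = {u for e in edges for u in e} | contacts | set(extra_proteins)
    return CellNetwork(label, proteins, edges, contacts)


def worked_fixture(name: str) -> SyntheticInstance:
    """Small hand-built instances used in examples and edge-case tests.

    - ``fig2_like``: two 6-protein cells with 3 contacts each and a small
      bipartite contact graph.
    - ``fig3_like``: a 10-pair matching, so the selected-pair count grows
      with the coverage level across the default alpha grid.
    - ``lonely_contact``: a contact protein with no intracellular edges
      (score 0, kept selectable by the normalization floor).
    - ``same_symbol``: one symbol present in both cells, forming a
      same-symbol intercellular pair.
    """
    if name == "fig2_like":
        net1 = _cell(
            "cell1",
            {("c1", "n1"), ("n1", "n2"), ("n2", "c2"), ("c2", "c3"), ("n1", "c3"),
             ("n2", "n3")},
            {"c1", "c2", "c3"},
        )
        net2 = _cell(
            "cell2",
            {("d1", "m1"), ("m1", "m2"), ("m2", "d2"), ("d1", "d3"), ("m1", "d3"),
             ("m2", "m3")},
            {"d1", "d2", "d3"},
        )
        inter = InterNetwork("cell1", "cell2", {
            ("c1", "d1"), ("c1", "d2"), ("c2", "d2"), ("c3", "d3"),
        })
        return SyntheticInstance(net1, net2, inter)

    if name == "fig3_like":
        # 10 disjoint intercellular pairs: each covers only itself, so
        # ceil(alpha * 10) pairs are needed at every alpha.
        c1 = {f"a{i}" for i in range(10)}
        c2 = {f"b{i}" for i in range(10)}
        edges1 = {(f"a{i}", "hub1") for i in range(10)}
        edges2 = {(f"b{i}", "hub2") for i in range(10)}
        net1 = _cell("cell1", edges1, c1)
        net2 = _cell("cell2", edges2, c2)
        inter = InterNetwork("cell1", "cell2", {(f"a{i}", f"b{i}") for i in range(10)})
        return SyntheticInstance(net1, net2, inter)

    if name == "lonely_contact":
        net1 = _cell(
            "cell1",
            {("c1", "n1"), ("n1", "n2")},
            {"c1", "cL"},
            extra_proteins={"cL"},
        )
        net2 = _cell("cell2", {("d1", "m1"), ("d2", "m1")}, {"d1", "d2"})
        inter = InterNetwork("cell1", "cell2", {("c1", "d1"), ("cL", "d2")})
        return SyntheticInstance(net1, net2, inter)

    if name == "same_symbol":
        net1 = _cell("cell1", {("X", "n1"), ("n1", "Y")}, {"X", "Y"})
        net2 = _cell("cell2", {("X", "m1"), ("m1", "Z")}, {"X", "Z"})
        inter = InterNetwork("cell1", "cell2", {("X", "X"), ("Y", "Z"), ("Y", "X")})
        return SyntheticInstance(net1, net2, inter)

    raise KeyError(f"unknown fixture {name!r}; known: fig2_like, fig3_like, "
                   "lonely_contact, same_symbol")
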