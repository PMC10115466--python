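"""Intracellular PPI networks, contact proteins, and the bipartite intercellular network.

A two-cell analysis starts from two intracellular protein-protein interaction
(PPI) edge lists, one proteome membership list per cell, and a ligand-receptor
pair table. Proteins that appear in a ligand-receptor pair whose partner is
present in the other cell's proteome are *contact proteins*; the induced
bipartite graph of such pairs is the intercellular network whose edges are both
the coverage targets and the candidate bridge pairs.

Identifiers are plain, case-sensitive, gene-symbol-like strings. The same
symbol occurring in both cells denotes two distinct nodes; cell-tagged
references (:class:`CellProteinRef`) disambiguate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "CellProteinRef",
    "CellNetwork",
    "InterNetwork",
    "NetworkError",
    "read_edge_list",
    "write_edge_list",
    "read_proteome",
    "read_lr_pairs",
    "restrict_to_proteome",
    "identify_contacts",
    "remove_unconnected",
]


class NetworkError(ValueError):
    """Raised for malformed input files or empty/degenerate networks."""


class CellProteinRef(NamedTuple):
    """A protein identifier tagged with the cell type it belongs to.

    Two refs are equal iff both the cell label and the symbol match, so an
    identical symbol in the two cells (e.g. an APP-APP bridge) yields two
    distinct nodes.
    """

    cell_label: str
    protein_id: str


def _norm_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class CellNetwork:
    """One cell type's undirected intracellular PPI graph plus its contact subset.

    Edges are stored as unordered, deduplicated pairs with no self-loops;
    every endpoint is a member of ``proteins`` and ``contacts`` is a subset
    of ``proteins``.
    """

    cell_label: str
    proteins: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    contacts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {_norm_edge(u, v) for u, v in self.edges}
        for u, v in self.edges:
            if u == v:
                raise NetworkError(f"self-loop edge {u!r} in cell {self.cell_label!r}")
            if u not in self.proteins or v not in self.proteins:
                raise NetworkError(
                    f"edge ({u!r}, {v!r}) has an endpoint outside the protein set "
                    f"of cell {self.cell_label!r}"
                )
        if not self.contacts <= self.proteins:
            stray = sorted(self.contacts - self.proteins)[:5]
            raise NetworkError(
                f"contacts not a subset of proteins in cell {self.cell_label!r}: {stray}"
            )

    @property
    def non_contacts(self) -> set[str]:
        return self.proteins - self.contacts

    def graph(self) -> nx.Graph:
        """The network as a :class:`networkx.Graph` (isolated nodes included)."""
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g

    def ref(self, protein_id: str) -> CellProteinRef:
        return CellProteinRef(self.cell_label, protein_id)


@dataclass
class InterNetwork:
    """Bipartite intercellular contact graph between two cell types.

    ``edges`` holds (cell-1 protein, cell-2 protein) pairs. Because candidate
    bridge pairs are restricted to connected pairs, the edge set doubles as
    the candidate pair set: ``|P| = |E|``.
    """

    cell1_label: str
    cell2_label: str
    edges: set[tuple[str, str]] = field(default_factory=set)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        """The candidate pair set P (identical to the edge set E)."""
        return self.edges

    def cell1_proteins(self) -> set[str]:
        return {u for u, _ in self.edges}

    def cell2_proteins(self) -> set[str]:
        return {v for _, v in self.edges}

    def refs(self, pair: tuple[str, str]) -> tuple[CellProteinRef, CellProteinRef]:
        u, v = pair
        return (CellProteinRef(self.cell1_label, u), CellProteinRef(self.cell2_label, v))


# ---------------------------------------------------------------------------
# File I/O: TSV edge lists, one-per-line proteome lists, two-column LR tables.


def _iter_tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_list(path: str | Path, cell_label: str) -> CellNetwork:
    """Read a two-column TSV of undirected PPI edges into a :class:`CellNetwork`.

    Duplicate rows and reversed duplicates collapse to one undirected edge;
    self-loop rows are dropped (with a logged count). '#'-prefixed comment
    lines are ignored.
    """
    edges: set[tuple[str, str]] = set()
    proteins: set[str] = set()
    n_self = 0
    n_rows = 0
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise NetworkError(f"{path}:{lineno}: expected two tab-separated identifiers")
        u, v = fields[0].strip(), fields[1].strip()
        n_rows += 1
        if u == v:
            n_self += 1
            continue
        proteins.update((u, v))
        edges.add(_norm_edge(u, v))
    if n_rows == 0:
        raise NetworkError(f"{path}: no edges found (empty network)")
    if n_self:
        logger.info("%s: dropped %d self-loop row(s)", path, n_self)
    return CellNetwork(cell_label=cell_label, proteins=proteins, edges=edges)


def write_edge_list(network: CellNetwork, path: str | Path) -> None:
    """Write the edge set as a sorted two-column TSV (round-trips with reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\n")
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def read_proteome(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line proteome membership list."""
    proteome: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                proteome.add(name)
    return proteome


def read_lr_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column ligand-receptor table; orientation is not meaningful."""
    pairs: set[tuple[str, str]] = set()
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise NetworkError(f"{path}:{lineno}: expected two tab-separated identifiers")
        pairs.add((fields[0].strip(), fields[1].strip()))
    return pairs


# ---------------------------------------------------------------------------
# Construction operations.


def restrict_to_proteome(network: CellNetwork, proteome: set[str]) -> CellNetwork:
    """Induced subgraph on the proteins present in the cell's proteome."""
    keep = network.proteins & proteome
    if not keep:
        raise NetworkError(
            f"proteome restriction leaves cell {network.cell_label!r} empty; "
            "check that the identifier namespaces match"
        )
    edges = {(u, v) for u, v in network.edges if u in keep and v in keep}
    return CellNetwork(
        cell_label=network.cell_label,
        proteins=keep,
        edges=edges,
        contacts=network.contacts & keep,
    )


def identify_contacts(
    net1: CellNetwork,
    net2: CellNetwork,
    lr_pairs: set[tuple[str, str]],
) -> tuple[CellNetwork, CellNetwork, InterNetwork]:
    """Flag contact proteins and build the intercellular network from LR pairs.

    A ligand-receptor pair (a, b) is tested in both orientations: it yields an
    intercellular edge (u, v) whenever one partner u is in cell 1's protein set
    and the other v is in cell 2's. The endpoints each cell contributes become
    its contact-protein set.
    """
    inter_edges: set[tuple[str, str]] = set()
    for a, b in lr_pairs:
        for u, v in ((a, b), (b, a)):
            if u in net1.proteins and v in net2.proteins:
                inter_edges.add((u, v))
    if not inter_edges:
        raise NetworkError(
            "no intercellular edges: no ligand-receptor pair maps into both "
            "proteomes; check the identifier namespaces"
        )
    contacts1 = {u for u, _ in inter_edges}
    contacts2 = {v for _, v in inter_edges}
    out1 = CellNetwork(net1.cell_label, set(net1.proteins), set(net1.edges), contacts1)
    out2 = CellNetwork(net2.cell_label, set(net2.proteins), set(net2.edges), contacts2)
    inter = InterNetwork(net1.cell_label, net2.cell_label, inter_edges)
    return out1, out2, inter


def remove_unconnected(network: CellNetwork) -> CellNetwork:
    """Drop proteins with intracellular degree 0 (contact flags drop with them).

    A contact protein removed here may still appear in the intercellular
    network; downstream scoring gives it a floor score so it remains
    selectable.
    """
    connected = {u for e in network.edges for u in e}
    dropped = network.proteins - connected
    if dropped:
        logger.info(
            "cell %s: removed %d unconnected node(s)", network.cell_label, len(dropped)
        )
    return CellNetwork(
        cell_label=network.cell_label,
        proteins=connected,
        edges=set(network.edges),
        contacts=network.contacts & connected,
    )
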