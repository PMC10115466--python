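"""End-to-end wiring: configuration, the two pipeline stages, and table I/O.

The analysis runs in two stages mirroring how the method is used in practice:

1. *score* — build the two intracellular networks from files, identify contact
   proteins and the intercellular network from the ligand-receptor table, drop
   unconnected nodes, compute centrality and the IIS, and write the per-cell
   IIS tables (the documented hand-off format).
2. *bridges* — assemble the ILP from the IIS tables, run the alpha sweep,
   rank pairs by OIS, and (when an annotation list is supplied) compare the
   selection's annotation rate against the random baseline.

Every run writes a provenance record (config, seed, input digests, package
version) sufficient to re-execute bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ilp import (
    DEFAULT_ALPHA_GRID,
    BridgeProblem,
    BridgeSolution,
    alpha_sweep,
    build_problem,
)
from .network import (
    CellNetwork,
    InterNetwork,
    identify_contacts,
    read_edge_list,
    read_lr_pairs,
    read_proteome,
    remove_unconnected,
    restrict_to_proteome,
)
from .ranking import association_rate, compute_ois, random_baseline
from .scoring import (
    DEFAULT_DAMPING,
    DEFAULT_EPSILON,
    DEFAULT_FLOOR,
    CentralityTable,
    IISTable,
    betweenness,
    compute_iis,
    normalize_iis,
    pagerank,
)

__all__ = [
    "RunConfig",
    "ScoredNetworks",
    "run_score",
    "run_bridges",
    "score_networks",
    "write_iis_table",
    "read_iis_table",
]


@dataclass
class RunConfig:
    """On-disk run configuration (YAML); round-trips losslessly."""

    cell1_edges: str = ""
    cell2_edges: str = ""
    cell1_proteome: str = ""
    cell2_proteome: str = ""
    lr_pairs: str = ""
    annotations: str | None = None
    cell1_label: str = "cell1"
    cell2_label: str = "cell2"
    alpha_grid: list[float] = field(default_factory=lambda: list(DEFAULT_ALPHA_GRID))
    centrality_metric: str = "pagerank"
    damping: float = DEFAULT_DAMPING
    epsilon: float = DEFAULT_EPSILON
    iis_floor: float = DEFAULT_FLOOR
    baseline_repetitions: int = 10_000
    seed: int = 0
    outdir: str = "brifin_out"

    def validate(self) -> None:
        if self.centrality_metric not in ("pagerank", "betweenness"):
            raise ValueError(f"unknown centrality metric {self.centrality_metric!r}")
        for a in self.alpha_grid:
            if not 0.0 < a <= 1.0:
                raise ValueError(f"alpha values must be in (0, 1], got {a}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ScoredNetworks:
    """Stage-1 output: pruned networks, centrality, and normalized IIS tables."""

    net1: CellNetwork
    net2: CellNetwork
    inter: InterNetwork
    centrality1: CentralityTable
    centrality2: CentralityTable
    iis1: IISTable
    iis2: IISTable


def _ensure_inter_endpoints(iis: IISTable, endpoints: set[str], floor: float) -> None:
    # a contact isolated intracellularly is dropped from the cell graph but
    # stays in the intercellular network; keep it selectable at the floor
    for p in endpoints:
        if p not in iis.normalized:
            iis.raw.setdefault(p, 0.0)
            iis.contributions.setdefault(p, {})
            iis.normalized[p] = floor


def score_networks(
    net1: CellNetwork,
    net2: CellNetwork,
    inter: InterNetwork,
    metric: str = "pagerank",
    damping: float = DEFAULT_DAMPING,
    epsilon: float = DEFAULT_EPSILON,
    floor: float = DEFAULT_FLOOR,
) -> ScoredNetworks:
    """Centrality + IIS for two cells whose contacts are already flagged."""
    net1 = remove_unconnected(net1)
    net2 = remove_unconnected(net2)
    tables = []
    for net in (net1, net2):
        if metric == "pagerank":
            cent = pagerank(net, damping=damping, epsilon=epsilon)
        else:
            cent = betweenness(net)
        iis = normalize_iis(compute_iis(net, cent), floor=floor)
        tables.append((cent, iis))
    (cent1, iis1), (cent2, iis2) = tables
    _ensure_inter_endpoints(iis1, inter.cell1_proteins(), floor)
    _ensure_inter_endpoints(iis2, inter.cell2_proteins(), floor)
    return ScoredNetworks(net1, net2, inter, cent1, cent2, iis1, iis2)


def _load_networks(cfg: RunConfig) -> tuple[CellNetwork, CellNetwork, InterNetwork]:
    net1 = read_edge_list(cfg.cell1_edges, cfg.cell1_label)
    net2 = read_edge_list(cfg.cell2_edges, cfg.cell2_label)
    net1 = restrict_to_proteome(net1, read_proteome(cfg.cell1_proteome))
    net2 = restrict_to_proteome(net2, read_proteome(cfg.cell2_proteome))
    return identify_contacts(net1, net2, read_lr_pairs(cfg.lr_pairs))


# ---------------------------------------------------------------------------
# Table I/O.


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_iis_table(iis: IISTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#metric={iis.metric}\tfloor={_fmt(iis.floor)}\n")
        fh.write("cell\tprotein\traw_iis\tnormalized_iis\n")
        for p in sorted(iis.normalized):
            fh.write(
                f"{iis.cell_label}\t{p}\t{_fmt(iis.raw.get(p, 0.0))}\t"
                f"{_fmt(iis.normalized[p])}\n"
            )


def read_iis_table(path: str | Path) -> IISTable:
    metric = "pagerank"
    floor = DEFAULT_FLOOR
    raw: dict[str, float] = {}
    normalized: dict[str, float] = {}
    cell = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#metric="):
                fields = line[1:].split("\t")
                metric = fields[0].split("=", 1)[1]
                floor = float(fields[1].split("=", 1)[1])
                continue
            if not line or line.startswith("#") or line.startswith("cell\t"):
                continue
            cell, protein, r, nrm = line.split("\t")
            raw[protein] = float(r)
            normalized[protein] = float(nrm)
    table = IISTable(cell_label=cell, metric=metric, raw=raw,
                     contributions={p: {} for p in raw}, floor=floor)
    table.normalized = normalized
    return table


def write_contributors(
    iis: IISTable, centrality: CentralityTable, path: str | Path, k: int = 20
) -> None:
    """Top-k additive IIS terms per contact protein, with distance and centrality."""
    from .scoring import top_contributors

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell\tcontact_protein\tcontributor\tdistance\tcentrality\tcontribution\n")
        for p in sorted(iis.contributions):
            for j, term in top_contributors(iis, p, k=k):
                pr = centrality.scores[j]
                d = int(round(pr / term)) if term > 0 else 0
                fh.write(
                    f"{iis.cell_label}\t{p}\t{j}\t{d}\t{_fmt(pr)}\t{_fmt(term)}\n"
                )


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """TSV [cell, protein, label] -> mapping cell label -> annotated proteins."""
    ann: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("cell\t"):
                continue
            fields = line.split("\t")
            ann.setdefault(fields[0], set()).add(fields[1])
    return ann


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _provenance(cfg: RunConfig, extra: dict) -> dict:
    digests = {}
    for key in ("cell1_edges", "cell2_edges", "cell1_proteome", "cell2_proteome",
                "lr_pairs", "annotations"):
        path = getattr(cfg, key)
        if path and Path(path).exists():
            digests[key] = _sha256(path)
    return {
        "package": "brifin",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "input_sha256": digests,
        **extra,
    }


# ---------------------------------------------------------------------------
# Stage drivers.


def run_score(cfg: RunConfig) -> ScoredNetworks:
    """Stage 1: networks -> IIS tables on disk (plus contributor tables)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net1, net2, inter = _load_networks(cfg)
    scored = score_networks(
        net1, net2, inter,
        metric=cfg.centrality_metric,
        damping=cfg.damping,
        epsilon=cfg.epsilon,
        floor=cfg.iis_floor,
    )
    write_iis_table(scored.iis1, outdir / "iis_cell1.tsv")
    write_iis_table(scored.iis2, outdir / "iis_cell2.tsv")
    write_contributors(scored.iis1, scored.centrality1, outdir / "contributors_cell1.tsv")
    write_contributors(scored.iis2, scored.centrality2, outdir / "contributors_cell2.tsv")
    record = _provenance(cfg, {
        "stage": "score",
        "network_sizes": {
            cfg.cell1_label: {"proteins": len(scored.net1.proteins),
                              "edges": len(scored.net1.edges),
                              "contacts": len(scored.net1.contacts)},
            cfg.cell2_label: {"proteins": len(scored.net2.proteins),
                              "edges": len(scored.net2.edges),
                              "contacts": len(scored.net2.contacts)},
        },
        "inter_edges": len(inter.edges),
    })
    with open(outdir / "run_score.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return scored


def run_bridges(cfg: RunConfig) -> dict[float, BridgeSolution]:
    """Stage 2: IIS tables -> per-alpha solutions, OIS ranking, baseline report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    iis1_path = outdir / "iis_cell1.tsv"
    if iis1_path.exists():
        iis1 = read_iis_table(iis1_path)
        iis2 = read_iis_table(outdir / "iis_cell2.tsv")
        _, _, inter = _load_networks(cfg)
    else:
        scored = run_score(cfg)
        iis1, iis2, inter = scored.iis1, scored.iis2, scored.inter

    problem = build_problem(inter, iis1, iis2)
    solutions = alpha_sweep(problem, tuple(cfg.alpha_grid))

    with open(outdir / "bridges.tsv", "w", encoding="utf-8") as fh:
        fh.write("alpha\tcell1_protein\tcell2_protein\ts_i\tcoverage_degree\tselected\n")
        for a in cfg.alpha_grid:
            sol = solutions[a]
            for p, cov in zip(problem.pairs, problem.cover):
                fh.write(
                    f"{_fmt(a)}\t{p[0]}\t{p[1]}\t{_fmt(problem.cost[p])}\t"
                    f"{len(cov)}\t{int(p in sol.selected)}\n"
                )

    with open(outdir / "ois.tsv", "w", encoding="utf-8") as fh:
        fh.write("cell1_protein\tcell2_protein\tcoverage_degree\tpair_score\tois\n")
        for rec in compute_ois(problem):
            fh.write(
                f"{rec.pair[0]}\t{rec.pair[1]}\t{rec.coverage_degree}\t"
                f"{_fmt(rec.pair_score)}\t{_fmt(rec.ois)}\n"
            )

    lines = ["alpha\tselected_pairs\tcovered_edges\tobjective"]
    for a in cfg.alpha_grid:
        sol = solutions[a]
        lines.append(
            f"{_fmt(a)}\t{len(sol.selected)}\t{len(sol.covered)}\t{_fmt(sol.objective)}"
        )
    (outdir / "summary.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    baseline_rows = None
    if cfg.annotations:
        ann = read_annotations(cfg.annotations)
        baseline_rows = []
        for a in cfg.alpha_grid:
            sol = solutions[a]
            rate = association_rate(sol, ann, cfg.cell1_label, cfg.cell2_label)
            base = random_baseline(
                problem, len(sol.selected), ann, cfg.cell1_label, cfg.cell2_label,
                repetitions=cfg.baseline_repetitions, seed=cfg.seed,
            )
            baseline_rows.append((a, rate, base.mean_rate))
        with open(outdir / "baseline.tsv", "w", encoding="utf-8") as fh:
            fh.write("alpha\tbrifin_rate\tbaseline_mean_rate\trepetitions\tseed\n")
            for a, rate, mean in baseline_rows:
                fh.write(
                    f"{_fmt(a)}\t{_fmt(rate)}\t{_fmt(mean)}\t"
                    f"{cfg.baseline_repetitions}\t{cfg.seed}\n"
                )

    record = _provenance(cfg, {
        "stage": "bridges",
        "n_pairs": problem.n,
        "solutions": {
            _fmt(a): {
                "selected": len(solutions[a].selected),
                "covered": len(solutions[a].covered),
                "objective": solutions[a].objective,
                "status": solutions[a].status,
            }
            for a in cfg.alpha_grid
        },
    })
    with open(outdir / "run_bridges.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return solutions
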