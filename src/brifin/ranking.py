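"""ILP-independent pair ranking (OIS) and the random-selection baseline.

The overall importance score (OIS) evaluates pairs individually: for pair i,
OIS_i = (coverage degree of i / max coverage degree) + (pair score of i / max
pair score), where the pair score is the sum of the two endpoints' normalized
IIS and the coverage degree is the number of intercellular edges the pair
covers. OIS ranks pairs without solving the ILP and therefore ignores the
complementarity between pairs that the ILP exploits.

The baseline statistic asks how often an equally sized *random* pair selection
would contain annotated (e.g. disease-associated) proteins: each repetition
draws the same number of pairs uniformly without replacement and measures the
fraction of distinct selected proteins that carry the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ilp import BridgeProblem, BridgeSolution, Pair
from .network import CellProteinRef

__all__ = [
    "OISRecord",
    "compute_ois",
    "selected_proteins",
    "association_rate",
    "random_baseline",
    "BaselineSummary",
]


@dataclass
class OISRecord:
    """One pair's coverage degree, pair score, and their normalized sum (OIS)."""

    pair: Pair
    coverage_degree: int
    pair_score: float
    ois: float


def compute_ois(problem: BridgeProblem) -> list[OISRecord]:
    """Score and sort all pairs by OIS, descending.

    Both components are divided by their maximum over the pairs, so each lies
    in (0, 1] and OIS in (0, 2]. Ties are broken lexicographically by pair.
    """
    degrees = {p: len(cov) for p, cov in zip(problem.pairs, problem.cover)}
    # pair score = 1 / s_i: the ILP cost is the inverse of the IIS sum
    scores = {p: 1.0 / problem.cost[p] for p in problem.pairs}
    max_deg = max(degrees.values())
    max_score = max(scores.values())
    records = [
        OISRecord(
            pair=p,
            coverage_degree=degrees[p],
            pair_score=scores[p],
            ois=degrees[p] / max_deg + scores[p] / max_score,
        )
        for p in problem.pairs
    ]
    records.sort(key=lambda r: (-r.ois, r.pair))
    return records


def selected_proteins(
    pairs: set[Pair], cell1_label: str, cell2_label: str
) -> set[CellProteinRef]:
    """Distinct cell-tagged proteins appearing in a pair selection."""
    refs: set[CellProteinRef] = set()
    for u, v in pairs:
        refs.add(CellProteinRef(cell1_label, u))
        refs.add(CellProteinRef(cell2_label, v))
    return refs


def association_rate(
    solution: BridgeSolution,
    annotated: dict[str, set[str]],
    cell1_label: str,
    cell2_label: str,
) -> float:
    """Fraction of distinct selected proteins carrying an annotation.

    A protein occurring in several selected pairs counts once (per cell);
    ``annotated`` maps each cell label to its annotated identifier set.
    """
    if not solution.selected:
        raise ValueError("empty selection has no association rate")
    refs = selected_proteins(solution.selected, cell1_label, cell2_label)
    hits = sum(1 for r in refs if r.protein_id in annotated.get(r.cell_label, set()))
    return hits / len(refs)


@dataclass
class BaselineSummary:
    """Monte-Carlo summary of the random-selection association rate."""

    mean_rate: float
    sd_rate: float
    repetitions: int
    n_pairs: int
    seed: int


def random_baseline(
    problem: BridgeProblem,
    n_pairs: int,
    annotated: dict[str, set[str]],
    cell1_label: str,
    cell2_label: str,
    repetitions: int = 10_000,
    seed: int = 0,
) -> BaselineSummary:
    """Mean association rate of ``n_pairs`` pairs drawn uniformly without replacement.

    Each of the ``repetitions`` draws samples from the candidate pair set and
    computes the annotated fraction over the distinct proteins of that draw
    (deduplicated within the repetition). Reproducible under ``seed``.
    """
    if not 1 <= n_pairs <= problem.n:
        raise ValueError(f"n_pairs must be in [1, {problem.n}], got {n_pairs}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    ann1 = annotated.get(cell1_label, set())
    ann2 = annotated.get(cell2_label, set())
    rates = np.empty(repetitions)
    n = problem.n
    for r in range(repetitions):
        draw = rng.choice(n, size=n_pairs, replace=False)
        refs = {("1", problem.pairs[i][0]) for i in draw}
        refs |= {("2", problem.pairs[i][1]) for i in draw}
        hits = sum(
            1
            for side, pid in refs
            if pid in (ann1 if side == "1" else ann2)
        )
        rates[r] = hits / len(refs)
    return BaselineSummary(
        mean_rate=float(rates.mean()),
        sd_rate=float(rates.std(ddof=1)) if repetitions > 1 else 0.0,
        repetitions=repetitions,
        n_pairs=n_pairs,
        seed=seed,
    )
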