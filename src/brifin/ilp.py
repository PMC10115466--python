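"""Bridge selection as an integer linear program.

Given the bipartite intercellular network, every intercellular edge is also a
candidate pair (P = E). Pair i has cost s_i = 1 / (sum of the two endpoints'
normalized IIS), and pair i covers edge j (c_ij = 1) when they share an
endpoint on the same cell side. Bridges are the cheapest pair set whose
selected pairs jointly cover at least a fraction alpha of the edges:

    min  sum_i x_i s_i
    s.t. x_i c_ij <= y_j              for all i, j
         sum_j y_j >= ceil(alpha |E|)
         y_j <= sum_i x_i c_ij        for all j
         x, y binary

At alpha = 1 this is the (NP-complete) set cover with pairs problem; for
smaller alpha it relaxes toward a maximum-quasi-clique-like selection. The
default backend is the exact HiGHS MILP solver via :func:`scipy.optimize.milp`;
a full-enumeration oracle (:func:`brute_force_bridges`) verifies it on small
instances.

Because protein pairs often have near-identical costs, many alternative optima
exist. Solutions are made reproducible by a staged tie-break: minimum cost,
then fewest pairs, then the lexicographically smallest selected set in the
problem's (sorted) pair order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import InterNetwork
from .scoring import IISTable

__all__ = [
    "BridgeProblem",
    "BridgeSolution",
    "SolverError",
    "pair_costs",
    "coverage_relation",
    "build_problem",
    "coverage_target",
    "solve_bridges",
    "brute_force_bridges",
    "alpha_sweep",
]

COST_TOL = 1e-9
DEFAULT_ALPHA_GRID = (0.1, 0.2, 0.4, 0.6, 0.8)

Pair = tuple[str, str]


class SolverError(RuntimeError):
    """Raised when the MILP backend fails to return a proven optimum."""


def pair_costs(inter: InterNetwork, iis1: IISTable, iis2: IISTable) -> dict[Pair, float]:
    """Cost s_i = 1 / (normalized IIS of u + normalized IIS of v) per pair (u, v)."""
    costs: dict[Pair, float] = {}
    for u, v in inter.edges:
        if u not in iis1.normalized:
            raise KeyError(f"no normalized IIS for {u!r} in cell {iis1.cell_label!r}")
        if v not in iis2.normalized:
            raise KeyError(f"no normalized IIS for {v!r} in cell {iis2.cell_label!r}")
        costs[(u, v)] = 1.0 / (iis1.normalized[u] + iis2.normalized[v])
    return costs


def covers(pair: Pair, edge: Pair) -> bool:
    """Pair (u, v) covers edge (a, b) iff u = a or v = b.

    The comparison is positional and therefore cell-respecting: a symbol
    shared by both cells never matches across sides.
    """
    return pair[0] == edge[0] or pair[1] == edge[1]


def coverage_relation(inter: InterNetwork) -> dict[Pair, set[Pair]]:
    """Map each pair to the set of intercellular edges it covers (itself included)."""
    edges = sorted(inter.edges)
    by_u: dict[str, list[Pair]] = {}
    by_v: dict[str, list[Pair]] = {}
    for e in edges:
        by_u.setdefault(e[0], []).append(e)
        by_v.setdefault(e[1], []).append(e)
    return {p: set(by_u[p[0]]) | set(by_v[p[1]]) for p in edges}


@dataclass
class BridgeProblem:
    """An ILP instance: pairs P (= edges E), costs s, coverage c, and alpha.

    ``pairs`` is sorted lexicographically and fixes the index order used for
    tie-breaking; ``cover[i]`` holds the indices of the edges pair i covers.
    """

    pairs: list[Pair]
    cost: dict[Pair, float]
    cover: list[frozenset[int]]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty problem: no candidate pairs")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for p in self.pairs:
            if self.cost[p] <= 0:
                raise ValueError(f"non-positive cost for pair {p}")
        for i, cov in enumerate(self.cover):
            if i not in cov:
                raise ValueError(f"pair {self.pairs[i]} does not cover its own edge")

    @property
    def n(self) -> int:
        return len(self.pairs)

    def costs_array(self) -> np.ndarray:
        return np.array([self.cost[p] for p in self.pairs])

    def objective_of(self, selected: set[Pair]) -> float:
        return sum(self.cost[p] for p in selected)

    def covered_by(self, selected: set[Pair]) -> set[Pair]:
        """Edges hit by a selection, recomputed from the coverage relation."""
        idx = {p: i for i, p in enumerate(self.pairs)}
        hit: set[int] = set()
        for p in selected:
            hit |= self.cover[idx[p]]
        return {self.pairs[j] for j in hit}


@dataclass
class BridgeSolution:
    """Selected pairs, the edges they cover, and the (recomputed) objective."""

    selected: set[Pair]
    covered: set[Pair]
    objective: float
    status: str
    alpha: float
    n_optimal_alternatives: int | None = field(default=None)


def build_problem(
    inter: InterNetwork, iis1: IISTable, iis2: IISTable, alpha: float = 1.0
) -> BridgeProblem:
    """Assemble costs and the coverage relation into a solvable instance."""
    pairs = sorted(inter.edges)
    idx = {p: i for i, p in enumerate(pairs)}
    rel = coverage_relation(inter)
    cover = [frozenset(idx[e] for e in rel[p]) for p in pairs]
    return BridgeProblem(pairs, pair_costs(inter, iis1, iis2), cover, alpha)


def coverage_target(alpha: float, n_edges: int) -> int:
    """Integer coverage threshold ceil(alpha * |E|), guarded against FP noise."""
    return max(0, math.ceil(alpha * n_edges - 1e-9))


# ---------------------------------------------------------------------------
# Exact MILP backend (HiGHS through scipy).


def _constraint_matrices(problem: BridgeProblem, k: int):
    """Sparse constraint blocks over variables [x_0..x_{n-1}, y_0..y_{n-1}]."""
    n = problem.n
    rows_ub, cols_ub, vals_ub = [], [], []
    r = 0
    # (1) x_i - y_j <= 0 for every covered (i, j)
    for i in range(n):
        for j in problem.cover[i]:
            rows_ub += [r, r]
            cols_ub += [i, n + j]
            vals_ub += [1.0, -1.0]
            r += 1
    # (3) y_j - sum_{i covers j} x_i <= 0
    covered_by_j: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in problem.cover[i]:
            covered_by_j[j].append(i)
    for j in range(n):
        rows_ub.append(r)
        cols_ub.append(n + j)
        vals_ub.append(1.0)
        for i in covered_by_j[j]:
            rows_ub.append(r)
            cols_ub.append(i)
            vals_ub.append(-1.0)
        r += 1
    a_ub = sparse.csr_matrix((vals_ub, (rows_ub, cols_ub)), shape=(r, 2 * n))
    # (2) sum_j y_j >= k
    a_cov = sparse.csr_matrix(
        (np.ones(n), (np.zeros(n, dtype=int), np.arange(n, 2 * n))), shape=(1, 2 * n)
    )
    return [
        LinearConstraint(a_ub, -np.inf, 0.0),
        LinearConstraint(a_cov, float(k), np.inf),
    ]


def _milp(c, constraints, n_vars, fixed: dict[int, float] | None = None):
    lb = np.zeros(n_vars)
    ub = np.ones(n_vars)
    if fixed:
        for i, val in fixed.items():
            lb[i] = ub[i] = val
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n_vars),
        bounds=Bounds(lb, ub),
    )
    return res


def solve_bridges(
    problem: BridgeProblem,
    alpha: float | None = None,
    tie_break: bool = True,
) -> BridgeSolution:
    """Exact optimum of the bridge ILP, with a deterministic tie-break.

    After the optimal objective z* is found, the returned selection is the one
    that, among selections with cost <= z* + 1e-9, has the fewest pairs and is
    lexicographically smallest in the problem's pair order (found by a
    cardinality re-solve and iterative index fixing). With ``tie_break=False``
    the first incumbent the solver proves optimal is returned.

    Always feasible for alpha <= 1, since selecting every pair covers every
    edge.
    """
    a = problem.alpha if alpha is None else alpha
    if not 0.0 < a <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {a}")
    n = problem.n
    k = coverage_target(a, n)
    constraints = _constraint_matrices(problem, k)
    s = problem.costs_array()
    c_cost = np.concatenate([s, np.zeros(n)])

    res = _milp(c_cost, constraints, 2 * n)
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP backend failed: {res.message}")
    x = np.round(res.x[:n]).astype(bool)
    selected = {problem.pairs[i] for i in np.flatnonzero(x)}
    z_star = problem.objective_of(selected)

    if tie_break:
        # stage 2: fewest pairs among cost-optimal selections
        budget = LinearConstraint(
            sparse.csr_matrix((s, (np.zeros(n, dtype=int), np.arange(n))), shape=(1, 2 * n)),
            -np.inf,
            z_star + COST_TOL,
        )
        c_card = np.concatenate([np.ones(n), np.zeros(n)])
        res2 = _milp(c_card, constraints + [budget], 2 * n)
        if res2.status != 0 or res2.x is None:
            raise SolverError(f"tie-break cardinality solve failed: {res2.message}")
        k_star = int(round(res2.x[:n].sum()))
        card = LinearConstraint(
            sparse.csr_matrix(
                (np.ones(n), (np.zeros(n, dtype=int), np.arange(n))), shape=(1, 2 * n)
            ),
            float(k_star),
            float(k_star),
        )
        # stage 3: lexicographically smallest index set, by greedy fixing
        fixed: dict[int, float] = {}
        chosen: list[int] = []
        witness = np.round(res2.x[:n]).astype(bool)
        for i in range(n):
            if len(chosen) == k_star:
                break
            trial = dict(fixed)
            trial[i] = 1.0
            res3 = _milp(
                np.zeros(2 * n), constraints + [budget, card], 2 * n, fixed=trial
            )
            if res3.status == 0 and res3.x is not None:
                fixed[i] = 1.0
                chosen.append(i)
                witness = np.round(res3.x[:n]).astype(bool)
            else:
                fixed[i] = 0.0
        selected = {problem.pairs[i] for i in np.flatnonzero(witness)}

    covered = problem.covered_by(selected)
    return BridgeSolution(
        selected=selected,
        covered=covered,
        objective=problem.objective_of(selected),
        status="optimal",
        alpha=a,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle.

BRUTE_FORCE_LIMIT = 20


def brute_force_bridges(
    problem: BridgeProblem,
    alpha: float | None = None,
    count_alternatives: bool = False,
) -> BridgeSolution:
    """Optimal selection by enumerating all 2^|P| subsets (|P| <= 20 enforced).

    Ties are broken by (fewest pairs, lexicographically smallest index set),
    matching :func:`solve_bridges`. With ``count_alternatives`` the number of
    enumerated selections whose cost is within tolerance of the optimum is
    recorded, quantifying how degenerate the instance is.
    """
    a = problem.alpha if alpha is None else alpha
    if not 0.0 < a <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {a}")
    n = problem.n
    if n > BRUTE_FORCE_LIMIT:
        raise ValueError(f"brute force limited to |P| <= {BRUTE_FORCE_LIMIT}, got {n}")
    k = coverage_target(a, n)
    masks = [sum(1 << j for j in cov) for cov in problem.cover]
    costs = [problem.cost[p] for p in problem.pairs]

    best_cost = math.inf
    feasible: list[tuple[float, tuple[int, ...]]] = []
    for subset in chain.from_iterable(
        combinations(range(n), r) for r in range(n + 1)
    ):
        hit = 0
        for i in subset:
            hit |= masks[i]
        if hit.bit_count() < k:
            continue
        cost = sum(costs[i] for i in subset)
        feasible.append((cost, subset))
        best_cost = min(best_cost, cost)
    if not feasible:
        raise SolverError("no feasible selection (unreachable for alpha <= 1)")

    tied = [(c, sub) for c, sub in feasible if c <= best_cost + COST_TOL]
    best = min(tied, key=lambda t: (len(t[1]), t[1]))
    selected = {problem.pairs[i] for i in best[1]}
    return BridgeSolution(
        selected=selected,
        covered=problem.covered_by(selected),
        objective=best[0],
        status="optimal",
        alpha=a,
        n_optimal_alternatives=len(tied) if count_alternatives else None,
    )


def alpha_sweep(
    problem: BridgeProblem,
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    tie_break: bool = True,
) -> dict[float, BridgeSolution]:
    """One tie-broken optimal solution per coverage level."""
    return {a: solve_bridges(problem, alpha=a, tie_break=tie_break) for a in alphas}
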