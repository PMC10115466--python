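# Methods

## Model and assumptions

`brifin` treats cell–cell communication as a two-layer graph problem. Each
cell type contributes an undirected, unweighted, simple intracellular PPI
graph restricted to that cell's proteome. A ligand–receptor table, matched by
plain case-sensitive identifier against both proteomes in both orientations,
induces the bipartite intercellular network; its endpoints are the contact
proteins and its edges double as the candidate bridge pairs. Identifier
mapping (UniProt ↔ symbol) is deliberately out of scope: inputs are assumed
to share one gene-symbol-like namespace, and a protein symbol occurring in
both cells denotes two distinct nodes (same-symbol bridges are legitimate).

Assumptions worth stating explicitly:

- All edges are undirected; ligand/receptor orientation carries no
  information here.
- Self-loops in input edge lists are dropped (distance and coverage
  semantics presuppose simple graphs).
- Degree-0 proteins are removed after contact identification. A contact
  protein that is isolated intracellularly but present in an intercellular
  edge is kept in the bipartite network with a floor score, so every
  intercellular edge remains coverable.

## Scoring

PageRank is computed on the full intracellular graph (before any pruning) by
power iteration: uniform start, dangling mass redistributed uniformly, sweep
repeated until the total L1 change falls below `epsilon`. Defaults are
damping 0.85 and epsilon 0.001 — the defaults of the network-analysis tools
practitioners use for PPI graphs — with a 1000-sweep cap treated as a
convergence error. Betweenness (Brandes, unnormalized, each unordered pair
counted once) is a drop-in alternative; only the induced score *ordering*
matters downstream, so its normalization convention is immaterial.

The IIS for contact protein *i* sums centrality/distance ratios over two
pruned graphs: non-contact proteins at BFS distance `d` in the graph with all
contact–contact edges removed, plus other contact proteins at BFS distance in
the contact-induced subgraph. Unreachable proteins contribute zero — in
particular, a contact protein whose only route to another contact runs
through a non-contact protein receives no second-term credit for it. The
self term is excluded (d = 0). Per-contact additive contributions are
retained so the top score contributors can be reported (default top 20).

Normalization divides by the per-cell maximum rather than min–max scaling:
min–max would map the weakest contact protein to zero and give its pairs
infinite cost, whereas max-scaling preserves ordering and strict positivity.
A floor of 1e-9 keeps isolated-but-contacted proteins selectable at a large
but finite cost.

## The ILP and its tie-break

The selection problem is solved exactly with HiGHS through
`scipy.optimize.milp`, single-threaded and deterministic. The redundant
constraint `x_i c_ij ≤ y_j` (implied at optimality by the coverage
constraint) is retained so the implemented model matches the stated
formulation constraint-for-constraint. The coverage threshold is
integerized as `⌈α·|E|⌉` (the coverage sum is integral), with a 1e-9 guard
against floating-point noise in the product.

Near-identical pair costs make alternative optima common. Reported solutions
are made reproducible by a staged tie-break: (1) optimal cost `z*`; (2) among
selections with cost ≤ `z*` + 1e-9, minimum cardinality; (3) among those, the
lexicographically smallest selected set in sorted pair order, found by greedy
index fixing (one feasibility MILP per index). The exhaustive oracle
(`brute_force_bridges`, guarded at |P| ≤ 20) applies the identical tie order,
so solver and oracle agree on the *set*, not just the objective; it can also
count how many optimal-cost alternatives an instance admits. Cost scaling by
a positive constant leaves the tie-broken selection unchanged.

OIS ranking normalizes each component (coverage degree, pair score) by its
maximum over pairs, so OIS ∈ (0, 2]; ties are ordered lexicographically.

## Random baseline

The baseline statistic draws, per repetition, as many pairs as the ILP
selected, uniformly without replacement from the candidate pairs, and
computes the fraction of *distinct* cell-tagged proteins in the draw that
carry an annotation (a protein in several drawn pairs counts once, and the
denominator deduplicates within each repetition, mirroring the definition
used for the ILP selection). 10 000 repetitions by default, one
`numpy.random.default_rng` generator seeded from the run configuration. On
instances with ≤ 8 pairs the Monte-Carlo mean is checked against exhaustive
enumeration of all draws.

## Synthetic data

The generator emulates the structure the method assumes, at desk scale:
heavy-tailed intracellular graphs (preferential-attachment growth with exact
edge counts; Erdős–Rényi available for contrast), a contact pool per cell,
and a sparse bipartite intercellular network over the pools. Defaults —
300/250 proteins, mean degree ~6, 15% contact fraction, 60 intercellular
edges, 2 planted bridges per cell — were chosen once as a realistic sparse
interactome miniature. Planted bridges receive extra intracellular edges to
the highest-degree proteins (raising centrality-over-distance mass) and a
~15% quota of the intercellular edges (raising coverage degree); they are the
operational ground truth for recovery experiments, since planted recovery is
a property of this construction, not an external claim.

What the generator does **not** emulate: identifier noise and mapping
ambiguity, false-positive/negative interactions, proteome incompleteness,
expression-level effects, and the literature-curation process behind real
disease-annotation lists. Passing recovery tests therefore demonstrates the
machinery is correct and directionally sound, not that real disease proteins
will be recovered at any particular rate.

## Numerical choices

- Cost/objective comparisons use an absolute tolerance of 1e-9.
- IIS raw scores equal the sum of stored contributions to 1e-9; PageRank
  sums to 1 within 1e-6 at the default epsilon.
- BFS distances are unit-weight hop counts; unreachable ⇒ contribution 0.
- All randomness flows through explicitly seeded `default_rng` generators;
  outputs are byte-identical across runs of the same configuration (tables
  are written in sorted order with fixed `%.12g` float formatting).

## Problem sizes used in validation

Solver/oracle equivalence is exercised on 100 random bipartite instances
with up to 12 pairs across α ∈ {0.1, 0.2, 0.4, 0.6, 0.8, 1.0}; IIS scoring on
50 random graphs up to 40 nodes against a first-principles BFS oracle;
recovery on 50 default-sized synthetic seeds at α = 0.1. These sizes keep
the exhaustive oracles exact while covering the combinatorial variety the
method encounters.

## Known limitations

- Exact MILP only; no approximation path for instances beyond what an exact
  solver handles (the pruning step is precisely what makes instances small).
- Single-namespace identifier matching; no ID translation.
- The candidate set is restricted to connected (interacting) pairs by
  design; non-adjacent pairs are never considered.
- Betweenness on large dense graphs is the slowest step (O(nm)); PageRank is
  the default for that reason as well.
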