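# Methods

## Problem and model

The package solves a graph-based combinatorial optimization problem:
extract maximal connected sub-networks ("key pathways") of an undirected
interaction network in which all nodes but at most K are active. Activity
is data-driven: each omics study is a binary indicator matrix (gene × case,
1 = significantly altered), and a gene is active for a study when its row
contains at most L non-active cases. Studies over different cohorts are
combined by a boolean formula over the per-matrix activity literals;
studies over the same cohort can alternatively be merged cell-wise into one
matrix before thresholding. Discretization of raw omics values into 0/1 is
deliberately out of scope — it depends on study design and platform and is
left to the user.

Two modelling assumptions are worth making explicit:

* **Activity is computed once, up front, for the whole node set.** The
  search never re-touches the matrices, so all solvers see the same frozen
  active/exception labelling. K models noise in the network, L noise in
  the omics data.
* **Exception budget semantics (INES).** K counts whole exception nodes
  per pathway. There is no global per-case exception budget summed over
  nodes; that alternative strategy is intentionally not implemented.

Prior knowledge enters through two node lists: positive-list nodes are
always treated as active (bypassing the data), negative-list nodes always
as exceptions (consuming budget but not forbidden). Positive and negative
lists must be disjoint; IDs absent from the network are ignored with a
warning.

## Parameters

| parameter | meaning | default |
|---|---|---|
| K | max exception nodes per pathway (count) | 0 |
| L (per matrix) | max non-active cases for an active gene; absolute count or percent of cases | required |
| formula | AND/OR/XOR tree over matrix names | required (single matrix: its name) |
| top_n | solutions reported by heuristics | 20 |
| seed | RNG seed for all stochastic components | 42 |

**Percent-to-count resolution uses the ceiling** of the exact fraction:
`L = ceil(p/100 · n_cases)`. For the two reference cohort sizes this gives
25% of 155 → 39 and 25% of 291 → 73. Both values are also consistent with
round-half-up, so the rule is an assumption; ceiling was chosen as the more
permissive reading of "at most L non-active cases" and is frozen here.
Absolute L above the case count clamps with a warning.

**Genes absent from a matrix** count every case as non-active, hence are
inactive there for any L below the case count. This is the conservative
choice: absence of measurement is not evidence of aberration. The gene
universe is always the network's node set; matrices are neither
intersected nor unioned beforehand.

**XOR and monotonicity.** Raising L can only grow each per-matrix active
set, so AND/OR-only formulas are monotone in every L. XOR breaks this
(activating the second operand deactivates the combination); the tests
assert both the monotone case and an explicit XOR counterexample. XOR over
more than two operands means the left-associative binary fold, not an
n-ary "exactly one".

**Cell-wise vs formula combination.** The two routes agree exactly for AND
at L = 0 (both demand all-ones rows in both matrices). For OR they do not,
even at L = 0: a gene covered case-by-case across the two matrices is
cellwise-OR active but formula-OR inactive. The cell-wise route is
strictly more permissive for OR; tests pin down both the AND equality and
the OR containment. Cell-wise combination requires identical case lists
and refuses otherwise, pointing the user to the per-matrix L mode.

## Solvers

**Exact.** Connected induced subgraphs are enumerated exactly once using
the fixed-node-order scheme (every set is grown from its smallest node;
candidates already branched on are banned from the remainder of the
subtree). Since the exception count is monotone under node addition, any
partial set that would exceed K is pruned. A set is reported when it is
valid and no single neighbor can be added: for this problem single-node
maximality coincides with set-inclusion maximality, because any connected
valid strict superset contains an addable neighbor whose addition keeps
the count at or below the superset's. Results are sorted by descending
size, ties by sorted node IDs. All-exception "pathways" are suppressed — a
module with no active node carries no signal. The enumerator refuses
networks above `max_nodes_for_exact` (default 25) unless overridden; it
exists as oracle and small-instance solver, not as a scalable algorithm.

**Greedy.** From each active-state start node, repeatedly add the best
frontier node: active-state before exception-state, then more active-state
neighbors outside the current set, then the lexicographically smaller ID.
Stops when no addition fits the budget, so results are valid and
single-node-maximal. Multi-start over all active nodes, deduplicated by
node-set equality (no overlap-based filtering), top-N reported.

**ACO.** Vertex pheromones τ start at `tau_max`. Each ant picks a start
among active nodes with probability ∝ τ^α, then grows the set choosing
frontier node u with probability ∝ τ_u^α · η_u^β, where η is 1 for
active-state and `epsilon_inactive` for exception-state nodes, subject to
the K budget. Per iteration, τ evaporates by ρ and the iteration-best
solution deposits |S_best|/|V| on its nodes; τ is clamped to
[tau_min, tau_max] (max–min scheme, keeps every node reachable). Defaults:
20 ants × 100 iterations, α=1, β=2, ρ=0.1, ε=0.1, τ ∈ [0.01, 1]. These
hyper-parameters and the update rule are this package's own design; no
equivalence with any other ACO variant is claimed — the guarantees are
validity of every emitted pathway and empirical optimality rates against
the exact oracle. One RNG stream per run, seeded; iteration-best
tie-breaks are by (size, sorted node IDs), so runs are byte-reproducible.

## Parameter sweep and node scores

The sweep solves every cell of the Cartesian grid K-values × per-matrix
L-lists, recomputing the activity profile per cell (L changes activity).
Cells are independent: heuristic cells derive their seed from
`SeedSequence(base_seed, spawn_key=(cell_index,))`, so extending the grid
never perturbs existing cells. The appearance score is

```
raw(v) = Σ_cells Σ_{P ∋ v} |P|        score(v) = raw(v) / max_raw
```

so it reflects both the number and the size of the pathways containing a
node; the best node scores exactly 1.0 whenever any pathway exists. The
concrete formula is this package's realization of a qualitative
"number and size" colouring rule; alternative weightings are not
configurable. Both the global aggregate and the per-cell solution files
are exported, since either view can drive a colouring.

## Synthetic fixtures

The generator emulates the statistical shape the method assumes, not any
real data set: a connected random graph (uniform random attachment tree
plus uniformly sampled extra edges), a planted connected module chosen as
a BFS ball from a random root (connectivity by construction, no rejection
sampling), and i.i.d. Bernoulli cells — planted genes active with
probability 0.9, background genes 0.05 by default. Cells are independent
across cases because the method only consumes per-row counts; correlation
structure, batch effects, realistic marginals and ID schemes of real
expression/methylation data are all absent, so passing tests demonstrate
algorithmic correctness and recoverability under the stated noise model,
not performance on real cohorts. The reference recovery scenario is the
generator's default: 100 nodes, 200 edges (mean degree 4, chosen once as
PPI-like sparsity), one 50-case study, module size 15, L=25%, K=2.

## Numerical and edge-case choices

* Percent resolution guards the ceiling against float error
  (`ceil(x − 1e-9)`), so 25% of 400 is exactly 100, not 101.
* Node-ID matching is byte-exact everywhere; no case folding.
* SIF accepts tab- or whitespace-delimited lines; tabs win when present so
  IDs containing spaces survive. The interaction-type column is ignored
  (the network is untyped and undirected). Self-loops are dropped and
  counted; duplicate edges collapse; single-token lines declare isolated
  nodes. The TSV indicator-matrix dialect (first column gene ID, optional
  header) is this package's own contract; compatibility with any other
  tool's matrix files is unverified.
* All text outputs are UTF-8 with `\n` line endings; node-score TSVs carry
  a `node_id<TAB>score` header and 6-decimal scores, and pathway JSON is
  sorted (size desc, then node IDs) — a bit-exact surface for the
  determinism tests.
* Empty results are not errors: a run with zero pathways exits 0 and
  reports an empty list.

## Problem sizes used in tests

The suite works at the scale where the exhaustive oracle is feasible:
oracle-agreement instances use 5–12 nodes (all-subsets enumeration),
heuristic soundness fixtures 12–25 nodes, and the recovery scenario 100
nodes. These sizes make every stochastic claim checkable against the exact
enumerator while keeping the whole suite fast.

## Known limitations

* The exact enumerator's memory and time grow exponentially; it is a
  correctness oracle, not a production solver.
* Greedy is deterministic and can miss optima that require temporarily
  "wasting" budget; ACO mitigates but does not eliminate this.
* No statistical evaluation of pathway significance is provided; output
  ranking is purely by size.
* Heuristic deduplication is by exact node-set equality, so near-duplicate
  solutions may crowd the top-N list.
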