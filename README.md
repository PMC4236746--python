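# kpminer

De novo network enrichment for multi-omics data: given an undirected
biological interaction network (e.g. protein–protein interactions) and one
or more **indicator matrices** — gene × case binary tables in which 1 marks
a significantly altered measurement — `kpminer` extracts **key pathways**:
maximal connected sub-networks in which all nodes but at most *K* are
*active*. It is aimed at systems biologists who have already discretized
their omics studies (expression, methylation, …) and want the aberrant
network modules those studies jointly support, without a GUI in the loop.

## The model

A gene *g* is **active for one study** *M* with case-exception threshold
*L* when its row contains at most *L* non-active cases:

```
active_M(g)  ⇔  |{ c : M[g, c] = 0 }| ≤ L
```

*L* can be an absolute count or a percentage of the study's cases
(resolved by ceiling, e.g. 25% of 155 cases → 39). Several studies with
different cohorts are merged by a boolean formula over these per-matrix
literals, e.g.

```
(M1 AND M2) OR (M3 AND M4)
```

with AND/OR/XOR as binary connectors (unparenthesized chains associate
left). Same-cohort studies can instead be merged cell-wise into a single
matrix (`Mc = M1 OR M2`). The search problem is then:

> find all maximal connected node sets *S* with
> |{ v ∈ S : v not active }| ≤ K.

The budget *K* counts whole exception nodes (the "individual node
exceptions" strategy). A **positive list** forces nodes to count as active
(they bypass the constraints); a **negative list** forces nodes to count
as exceptions (they drain the budget but are not forbidden). Solvers:

* `exact` — branch-and-bound enumeration of *all* maximal valid pathways;
  the correctness oracle, capped at small networks (default ≤ 25 nodes);
* `greedy` — deterministic best-first expansion from every active node;
* `aco` — ant colony optimization: probabilistic growth biased by vertex
  pheromones reinforced on each iteration's best solution; seeded and
  fully reproducible.

A **parameter sweep** solves a grid of (K, L) combinations and aggregates a
per-node appearance score (sum of the sizes of all pathways containing the
node, normalized to max 1.0) — a continuous node attribute for
color-intensity visualization, e.g. in Cytoscape.

## Worked example

Generate a synthetic fixture with a planted 10-gene module in a 40-node
network (30 cases, noisy activity), then mine it:

```sh
kpminer fixtures --out fx --seed 11 --n-nodes 40 --n-edges 70 \
    --n-cases 30 --module-size 10
kpminer run --network fx/network.sif --matrix M1=fx/matrix_M1.tsv \
    --l M1=25% --formula M1 --k 2 --algorithm greedy --out-dir out
```

The run logs (stderr):

```
INFO network: 40 nodes, 70 edges
INFO matrix M1: 40 genes, 30 cases, resolved L=8
INFO formula M1: 10/40 network nodes active (25.0%)
INFO 1 pathway(s) written to out
```

`--l M1=25%` resolved to L=8 (ceiling of 25% of 30 cases), under which
exactly the 10 planted genes are active. `out/pathways.json` reports one
key pathway of **size 12**: the 10 planted genes plus the two exception
nodes `n01` and `n03` that the K=2 budget spent to bridge them into a
single connected module — precisely what the exception mechanism is for.
Each pathway is also written as GraphML with a boolean `exception` node
attribute.

Other subcommands: `kpminer sweep` (grid search, writes per-cell JSON and
`node_scores.tsv`), `kpminer validate` (input checks and ID-overlap
statistics, read-only). `kpminer run --config run.yaml` reads any flag
from YAML; explicit flags override it.

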