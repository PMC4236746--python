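"""Synthetic networks and indicator matrices with planted key pathways.

Real inputs to this method are a protein-protein interaction network and
discretized omics studies; neither is bundled here. Instead, fixtures plant
a known module: a connected random graph (random spanning tree plus extra
edges, PPI-like sparsity), a connected node subset chosen by a seeded BFS
ball, and indicator matrices filled i.i.d. Bernoulli per cell — planted
genes active with high probability, background genes with low probability.
Cells are independent across cases because the method only ever consumes
per-row counts; case-correlation structure would add nothing testable.

Defaults are the package's reference recovery scenario: a 100-node /
200-edge network, one 50-case study, a planted module of 15 genes, activity
probabilities 0.9 (planted) vs 0.05 (background).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import IndicatorMatrix, Network, write_indicator_matrix, write_network

__all__ = ["FixtureSpec", "generate_network", "plant_module", "make_fixture", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    n_nodes: int = 100
    n_edges: int = 200
    n_cases: tuple[int, ...] = (50,)  # one entry per indicator matrix
    planted_module_size: int = 15
    background_active_prob: float = 0.05
    planted_active_prob: float = 0.9
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("need at least one node")
        if self.planted_module_size > self.n_nodes:
            raise ValueError("planted module larger than the network")
        if not self.planted_active_prob > self.background_active_prob:
            raise ValueError("planted_active_prob must exceed background_active_prob")
        if any(c < 1 for c in self.n_cases):
            raise ValueError("every matrix needs at least one case")
        object.__setattr__(self, "n_cases", tuple(self.n_cases))


def _node_name(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def generate_network(spec: FixtureSpec) -> Network:
    """Connected random graph: a uniform random attachment tree plus extra
    edges sampled uniformly from the remaining non-edges. Deterministic per
    seed."""
    n, m = spec.n_nodes, spec.n_edges
    max_edges = n * (n - 1) // 2
    if m < n - 1 or m > max_edges:
        raise ValueError(f"n_edges={m} infeasible for {n} nodes (need {n - 1}..{max_edges})")
    rng = np.random.default_rng(spec.seed)
    width = len(str(n - 1))
    names = [_node_name(i, width) for i in range(n)]
    perm = rng.permutation(n)
    edges: set[tuple[int, int]] = set()
    for pos in range(1, n):
        a = int(perm[pos])
        b = int(perm[rng.integers(0, pos)])
        edges.add((min(a, b), max(a, b)))
    # top up with uniformly sampled non-edges
    while len(edges) < m:
        a = int(rng.integers(0, n))
        b = int(rng.integers(0, n))
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return Network(nodes=names, edges=[(names[a], names[b]) for a, b in sorted(edges)])


def plant_module(network: Network, spec: FixtureSpec) -> tuple[frozenset[str], list[IndicatorMatrix]]:
    """Choose a connected planted node set (BFS ball from a random root) and
    fill one indicator matrix per ``n_cases`` entry with i.i.d. Bernoulli
    cells: planted genes at ``planted_active_prob``, background genes at
    ``background_active_prob``."""
    if spec.planted_module_size > len(network.nodes):
        raise ValueError("planted module larger than the network")
    rng = np.random.default_rng(spec.seed + 1)  # independent of topology stream
    nodes = sorted(network.nodes)
    root = nodes[int(rng.integers(0, len(nodes)))]
    planted: list[str] = [root]
    planted_set = {root}
    queue = [root]
    while queue and len(planted) < spec.planted_module_size:
        v = queue.pop(0)
        for u in sorted(network.neighbors(v)):
            if u not in planted_set:
                planted_set.add(u)
                planted.append(u)
                queue.append(u)
                if len(planted) >= spec.planted_module_size:
                    break
    # a small component can truncate the ball; the graph is connected by
    # construction, so this only happens for degenerate specs
    planted_frozen = frozenset(planted)
    matrices: list[IndicatorMatrix] = []
    for mi, n_cases in enumerate(spec.n_cases, start=1):
        probs = np.array(
            [spec.planted_active_prob if v in planted_frozen else spec.background_active_prob
             for v in nodes]
        )
        cells = (rng.random((len(nodes), n_cases)) < probs[:, None]).astype("int8")
        frame = pd.DataFrame(
            cells, index=nodes, columns=[f"case_{i + 1}" for i in range(n_cases)]
        )
        matrices.append(IndicatorMatrix(name=f"M{mi}", values=frame))
    return planted_frozen, matrices


def make_fixture(spec: FixtureSpec | None = None) -> tuple[Network, frozenset[str], list[IndicatorMatrix]]:
    """Network + planted module + matrices in one call."""
    if spec is None:
        spec = FixtureSpec()
    network = generate_network(spec)
    planted, matrices = plant_module(network, spec)
    return network, planted, matrices


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Materialize a fixture on disk: SIF network, TSV matrices, and a
    ground-truth JSON naming the planted nodes. Returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, planted, matrices = make_fixture(spec)
    files: dict[str, str] = {}
    net_path = out_dir / "network.sif"
    write_network(network, net_path, format="sif")
    files["network"] = net_path.name
    for matrix in matrices:
        mpath = out_dir / f"matrix_{matrix.name}.tsv"
        write_indicator_matrix(matrix, mpath)
        files[matrix.name] = mpath.name
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "planted_nodes": sorted(planted),
                "spec": {
                    "n_nodes": spec.n_nodes,
                    "n_edges": spec.n_edges,
                    "n_cases": list(spec.n_cases),
                    "planted_module_size": spec.planted_module_size,
                    "background_active_prob": spec.background_active_prob,
                    "planted_active_prob": spec.planted_active_prob,
                    "seed": spec.seed,
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    files["ground_truth"] = truth_path.name
    return files
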