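"""Parameter sweeps over (K, L) grids and per-node appearance scores.

Choosing K (noise in the network) and L (noise in the omics data) is the
hard part of using the method in practice. The sweep pre-computes solutions
for a grid of (K, L-vector) combinations; per-node appearance scores — the
sum of the sizes of all key pathways containing a node, across all grid
cells, normalized so the best node scores exactly 1 — then drive a
color-intensity visualization: the higher K and L, the larger the
highlighted regions of the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .activity import CaseExceptionSpec, CombinedFormula, compute_activity, resolve_case_exceptions
from .io_formats import IndicatorMatrix, Network
from .search_exact import KeyPathway, SearchParameters, enumerate_maximal_pathways
from .search_heuristic import AcoConfig, aco_search, greedy_search

__all__ = ["SweepGrid", "SweepCell", "SweepResult", "run_sweep", "node_scores", "cell_seed"]


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian grid: K values x per-matrix lists of L specs."""

    k_values: tuple[int, ...]
    l_specs: Mapping[str, tuple[CaseExceptionSpec, ...]]

    def __post_init__(self) -> None:
        if not self.k_values:
            raise ValueError("grid needs at least one K value")
        if any(k < 0 for k in self.k_values):
            raise ValueError("K values must be >= 0")
        if not self.l_specs or any(not specs for specs in self.l_specs.values()):
            raise ValueError("grid needs at least one L spec per matrix")
        object.__setattr__(self, "k_values", tuple(self.k_values))
        object.__setattr__(
            self, "l_specs", {name: tuple(specs) for name, specs in self.l_specs.items()}
        )

    def cells(self) -> list[tuple[int, tuple[tuple[str, CaseExceptionSpec], ...]]]:
        names = sorted(self.l_specs)
        out = []
        for k in self.k_values:
            for combo in itertools.product(*(self.l_specs[n] for n in names)):
                out.append((k, tuple(zip(names, combo))))
        return out


@dataclass(frozen=True)
class SweepCell:
    """One grid cell: the parameters it was solved under and its solutions."""

    k: int
    l_values: tuple[tuple[str, int], ...]  # resolved per-matrix counts
    l_specs: tuple[tuple[str, CaseExceptionSpec], ...]
    pathways: tuple[KeyPathway, ...]


@dataclass(frozen=True)
class SweepResult:
    cells: tuple[SweepCell, ...]
    node_scores: Mapping[str, float] = field(default_factory=dict)

    def max_size_per_cell(self) -> list[int]:
        return [max((p.size for p in c.pathways), default=0) for c in self.cells]


def cell_seed(base_seed: int, cell_index: int) -> int:
    """Derive a per-cell seed so cells are independent yet reproducible."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def node_scores(cells: Sequence[SweepCell]) -> dict[str, float]:
    """Appearance score per node: sum of |P| over all containing pathways in
    all cells, normalized by the maximum (0 everywhere if no pathways)."""
    raw: dict[str, float] = {}
    for cell in cells:
        for pw in cell.pathways:
            for v in pw.nodes:
                raw[v] = raw.get(v, 0.0) + pw.size
    if not raw:
        return {}
    max_raw = max(raw.values())
    return {v: r / max_raw for v, r in raw.items()}


def run_sweep(
    network: Network,
    matrices: Mapping[str, IndicatorMatrix],
    formula: CombinedFormula,
    grid: SweepGrid,
    algorithm: str = "greedy",
    params: SearchParameters | None = None,
    seed: int = 42,
    top_n: int = 20,
    aco_config: AcoConfig | None = None,
    max_nodes_for_exact: int = 25,
) -> SweepResult:
    """Solve every grid cell independently and aggregate node scores.

    Each cell recomputes the activity profile (L changes activity) and runs
    the chosen solver; heuristic cells derive their own seeds from the base
    seed and the cell index, so no state leaks between cells and the whole
    sweep is reproducible.
    """
    if params is None:
        params = SearchParameters()
    if algorithm not in ("exact", "greedy", "aco"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    cells: list[SweepCell] = []
    for idx, (k, l_combo) in enumerate(grid.cells()):
        l_values = tuple(
            (name, resolve_case_exceptions(spec, matrices[name].n_cases))
            for name, spec in l_combo
        )
        try:
            profile = compute_activity(network.nodes, matrices, dict(l_values), formula)
            cell_params = SearchParameters(k=k, positive=params.positive, negative=params.negative)
            if algorithm == "exact":
                pathways = enumerate_maximal_pathways(
                    network, profile, cell_params, max_nodes_for_exact=max_nodes_for_exact
                )
            elif algorithm == "greedy":
                pathways = greedy_search(network, profile, cell_params, top_n=top_n)
            else:
                base = aco_config if aco_config is not None else AcoConfig()
                cfg = AcoConfig(
                    n_ants=base.n_ants,
                    n_iterations=base.n_iterations,
                    alpha=base.alpha,
                    beta=base.beta,
                    rho=base.rho,
                    tau_min=base.tau_min,
                    tau_max=base.tau_max,
                    epsilon_inactive=base.epsilon_inactive,
                    seed=cell_seed(seed, idx),
                )
                pathways = aco_search(network, profile, cell_params, config=cfg, top_n=top_n)
        except Exception as exc:
            raise RuntimeError(f"sweep cell (K={k}, L={dict(l_values)}) failed: {exc}") from exc
        cells.append(
            SweepCell(k=k, l_values=l_values, l_specs=l_combo, pathways=tuple(pathways))
        )
    scores = node_scores(cells)
    return SweepResult(cells=tuple(cells), node_scores=scores)
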