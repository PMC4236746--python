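"""Scalable key-pathway solvers: multi-start greedy expansion and ant colony
optimization (ACO).

Both solve the same problem as the exact enumerator — maximal connected
sub-networks with at most K exception-state nodes — but scale to networks
where exhaustive enumeration is hopeless. Greedy is deterministic; ACO is a
population heuristic in which probabilistic solution growth is biased by
vertex pheromones reinforced on each iteration's best solution. Both are
fully reproducible for a fixed seed (single RNG stream per run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityProfile
from .io_formats import Network
from .search_exact import (
    ACTIVE,
    EXCEPTION,
    KeyPathway,
    SearchParameters,
    effective_state,
)

__all__ = ["AcoConfig", "greedy_expand", "greedy_search", "aco_search"]


@dataclass(frozen=True)
class AcoConfig:
    """ACO hyper-parameters.

    ``alpha`` exponentiates pheromone, ``beta`` the static desirability
    (1 for active-state nodes, ``epsilon_inactive`` for exception-state
    nodes), ``rho`` is the per-iteration evaporation rate, and pheromones
    are clamped to [tau_min, tau_max] (a max-min scheme that keeps every
    node reachable).
    """

    n_ants: int = 20
    n_iterations: int = 100
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.1
    tau_min: float = 0.01
    tau_max: float = 1.0
    epsilon_inactive: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ValueError("n_ants and n_iterations must be >= 1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (0,1), got {self.rho}")
        if not (0.0 < self.tau_min <= self.tau_max):
            raise ValueError("require 0 < tau_min <= tau_max")
        if not (0.0 < self.epsilon_inactive < 1.0):
            raise ValueError("epsilon_inactive must lie in (0,1)")


def _states(network: Network, profile: ActivityProfile, params: SearchParameters) -> dict[str, str]:
    return {v: effective_state(v, profile, params) for v in network.nodes}


def greedy_expand(
    start: str,
    network: Network,
    profile: ActivityProfile,
    params: SearchParameters,
) -> KeyPathway:
    """Grow a single pathway from ``start`` by best-first frontier addition.

    Preference order for the next node: active-state before exception-state,
    then more active-state neighbors outside the current set, then the
    lexicographically smaller ID. Expansion stops when no addition keeps the
    exception count within K; the result is valid and single-node-maximal.
    """
    if start not in network:
        raise ValueError(f"start node {start!r} not in network")
    state = _states(network, profile, params)
    if state[start] != ACTIVE:
        raise ValueError(f"start node {start!r} has exception state; start from an active node")
    adj = network.adj
    current: set[str] = {start}
    exc_count = 0
    frontier: set[str] = set(adj[start])

    def preference(u: str) -> tuple[int, int, str]:
        outside_active = sum(
            1 for w in adj[u] if w not in current and state[w] == ACTIVE
        )
        return (0 if state[u] == ACTIVE else 1, -outside_active, u)

    while True:
        addable = [
            u for u in frontier
            if state[u] == ACTIVE or exc_count < params.k
        ]
        if not addable:
            break
        best = min(addable, key=preference)
        current.add(best)
        if state[best] == EXCEPTION:
            exc_count += 1
        frontier |= adj[best] - current
        frontier.discard(best)

    exceptions = frozenset(v for v in current if state[v] == EXCEPTION)
    return KeyPathway(nodes=frozenset(current), exceptions=exceptions)


def _top_n(pathways: dict[frozenset[str], KeyPathway], top_n: int) -> list[KeyPathway]:
    ordered = sorted(pathways.values(), key=KeyPathway.sort_key)
    return ordered[:top_n]


def greedy_search(
    network: Network,
    profile: ActivityProfile,
    params: SearchParameters,
    top_n: int = 20,
) -> list[KeyPathway]:
    """Greedy expansion from every active-state node; distinct solutions
    ranked by descending size (ties by sorted node IDs)."""
    state = _states(network, profile, params)
    found: dict[frozenset[str], KeyPathway] = {}
    for start in sorted(network.nodes):
        if state[start] != ACTIVE:
            continue
        pw = greedy_expand(start, network, profile, params)
        found.setdefault(pw.nodes, pw)
    return _top_n(found, top_n)


def aco_search(
    network: Network,
    profile: ActivityProfile,
    params: SearchParameters,
    config: AcoConfig | None = None,
    top_n: int = 20,
    return_history: bool = False,
):
    """Ant-colony search for large key pathways.

    Vertex pheromones start at ``tau_max``. Each iteration, every ant picks
    a start among active-state nodes with probability proportional to
    ``tau^alpha``, then grows the set like greedy expansion but chooses the
    next frontier node u with probability proportional to
    ``tau_u^alpha * eta_u^beta`` (eta = 1 for active state,
    ``epsilon_inactive`` for exception state), subject to the K budget.
    After each iteration pheromones evaporate by rho and the iteration-best
    solution deposits ``|S_best| / |V|`` on its nodes, clamped to
    [tau_min, tau_max]. Returns the ``top_n`` distinct best solutions found
    across all iterations; with ``return_history=True`` also the best-so-far
    size after each iteration.
    """
    if config is None:
        config = AcoConfig()
    state = _states(network, profile, params)
    nodes = sorted(network.nodes)
    active_nodes = [v for v in nodes if state[v] == ACTIVE]
    if not active_nodes:
        return ([], []) if return_history else []
    adj = network.adj
    rng = np.random.default_rng(config.seed)
    tau = {v: config.tau_max for v in nodes}
    eta_pow = {
        v: (1.0 if state[v] == ACTIVE else config.epsilon_inactive) ** config.beta
        for v in nodes
    }
    found: dict[frozenset[str], KeyPathway] = {}
    history: list[int] = []
    best_so_far = 0
    n_total = len(nodes)

    def walk() -> frozenset[str]:
        weights = np.array([tau[v] ** config.alpha for v in active_nodes])
        start = active_nodes[rng.choice(len(active_nodes), p=weights / weights.sum())]
        current: set[str] = {start}
        exc_count = 0
        frontier: set[str] = set(adj[start])
        while True:
            addable = sorted(
                u for u in frontier if state[u] == ACTIVE or exc_count < params.k
            )
            if not addable:
                break
            w = np.array([tau[u] ** config.alpha * eta_pow[u] for u in addable])
            nxt = addable[rng.choice(len(addable), p=w / w.sum())]
            current.add(nxt)
            if state[nxt] == EXCEPTION:
                exc_count += 1
            frontier |= adj[nxt] - current
            frontier.discard(nxt)
        return frozenset(current)

    for _ in range(config.n_iterations):
        iter_best: frozenset[str] | None = None
        for _ant in range(config.n_ants):
            solution = walk()
            if solution not in found:
                found[solution] = KeyPathway(
                    nodes=solution,
                    exceptions=frozenset(v for v in solution if state[v] == EXCEPTION),
                )
            if iter_best is None or (
                (-len(solution), tuple(sorted(solution)))
                < (-len(iter_best), tuple(sorted(iter_best)))
            ):
                iter_best = solution
        for v in nodes:
            tau[v] *= 1.0 - config.rho
        deposit = len(iter_best) / n_total
        for v in iter_best:
            tau[v] += deposit
        for v in nodes:
            tau[v] = min(config.tau_max, max(config.tau_min, tau[v]))
        best_so_far = max(best_so_far, len(iter_best))
        history.append(best_so_far)

    results = _top_n(found, top_n)
    return (results, history) if return_history else results
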