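"""Exact enumeration of maximal key pathways (small instances).

The optimization problem: find maximal connected sub-networks in which all
nodes but at most K are active. K budgets whole exception nodes — the
"individual node exceptions" (INES) strategy; there is no global per-case
budget. Positive-list nodes are always treated as active (they bypass the
constraint and never consume K); negative-list nodes are always exceptions
(they consume K if included, but are not forbidden).

Enumeration visits every connected induced subgraph at most once via the
standard fixed-order scheme (each set is generated from its smallest node,
with previously-branched candidates banned), pruning any partial set whose
exception count already exceeds K — the count is monotone under node
addition, so pruning is safe. This solver doubles as the correctness oracle
for the heuristics and as the default solver below a size cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .activity import ActivityProfile
from .io_formats import Network

__all__ = [
    "ACTIVE",
    "EXCEPTION",
    "SearchParameters",
    "KeyPathway",
    "effective_state",
    "exception_nodes",
    "is_valid_pathway",
    "make_pathway",
    "enumerate_maximal_pathways",
]

ACTIVE = "active"
EXCEPTION = "exception"


@dataclass(frozen=True)
class SearchParameters:
    """K (node-exception budget) plus the prior-knowledge node lists."""

    k: int = 0
    positive: frozenset[str] = field(default_factory=frozenset)
    negative: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"K must be >= 0, got {self.k}")
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        overlap = self.positive & self.negative
        if overlap:
            raise ValueError(f"positive and negative lists overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class KeyPathway:
    """A connected node set with its exception nodes (the validity certificate)."""

    nodes: frozenset[str]
    exceptions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("a key pathway cannot be empty")
        if not self.exceptions <= self.nodes:
            raise ValueError("exceptions must be a subset of the pathway nodes")

    @property
    def size(self) -> int:
        return len(self.nodes)

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        # descending size, ties broken lexicographically by sorted node IDs
        return (-len(self.nodes), tuple(sorted(self.nodes)))


def effective_state(v: str, profile: ActivityProfile, params: SearchParameters) -> str:
    """State of a node after applying the prior-knowledge lists.

    Positive-list membership forces ACTIVE regardless of the data;
    negative-list membership forces EXCEPTION regardless of the data;
    otherwise the activity profile decides.
    """
    if v in params.positive:
        return ACTIVE
    if v in params.negative:
        return EXCEPTION
    return ACTIVE if profile.active[v] else EXCEPTION


def exception_nodes(nodes, profile: ActivityProfile, params: SearchParameters) -> frozenset[str]:
    return frozenset(
        v for v in nodes if effective_state(v, profile, params) == EXCEPTION
    )


def is_valid_pathway(
    nodes, network: Network, profile: ActivityProfile, params: SearchParameters
) -> bool:
    """True iff ``nodes`` is non-empty, induces a connected subgraph, and
    contains at most K exception-state nodes."""
    node_set = set(nodes)
    if not node_set or not node_set <= network.nodes:
        return False
    if len(exception_nodes(node_set, profile, params)) > params.k:
        return False
    return network.is_connected_subset(node_set)


def make_pathway(nodes, profile: ActivityProfile, params: SearchParameters) -> KeyPathway:
    node_set = frozenset(nodes)
    return KeyPathway(nodes=node_set, exceptions=exception_nodes(node_set, profile, params))


def enumerate_maximal_pathways(
    network: Network,
    profile: ActivityProfile,
    params: SearchParameters,
    max_nodes_for_exact: int = 25,
) -> list[KeyPathway]:
    """All maximal valid key pathways, sorted by descending size.

    A returned set S is valid (connected, <= K exceptions, at least one
    active-state node) and maximal: no strict valid superset exists.
    Maximality is checked against single-node additions, which is equivalent
    here — any connected valid superset contains an addable neighbor of S,
    and adding it cannot raise the exception count past the superset's.

    Raises on instances above ``max_nodes_for_exact``; pass a larger cap to
    override, or use the heuristic solvers.
    """
    if len(network.nodes) > max_nodes_for_exact:
        raise ValueError(
            f"network has {len(network.nodes)} nodes, above the exact-search cap of "
            f"{max_nodes_for_exact}; raise max_nodes_for_exact or use greedy/ACO"
        )
    state = {v: effective_state(v, profile, params) for v in network.nodes}
    k = params.k
    adj = network.adj
    order = {v: i for i, v in enumerate(sorted(network.nodes))}
    results: list[frozenset[str]] = []

    def neighbor_cost(u: str) -> int:
        return 1 if state[u] == EXCEPTION else 0

    def rec(current: set[str], exc_count: int, frontier: set[str], banned: frozenset[str]) -> None:
        results.append(frozenset(current))
        local_banned = set(banned)
        for u in sorted(frontier):
            cost = exc_count + neighbor_cost(u)
            if cost <= k:
                new_frontier = (frontier | (adj[u] - current)) - local_banned
                new_frontier.discard(u)
                current.add(u)
                rec(current, cost, new_frontier, frozenset(local_banned))
                current.remove(u)
            local_banned.add(u)

    for start in sorted(network.nodes):
        banned = frozenset(v for v in network.nodes if order[v] < order[start])
        start_cost = neighbor_cost(start)
        if start_cost > k:
            continue
        rec({start}, start_cost, adj[start] - banned, banned)

    maximal: list[KeyPathway] = []
    for node_set in results:
        exc = frozenset(v for v in node_set if state[v] == EXCEPTION)
        if len(exc) == len(node_set):
            continue  # pathways must carry signal: at least one active node
        boundary = set().union(*(adj[v] for v in node_set)) - node_set
        extendable = any(
            state[u] == ACTIVE or len(exc) < k for u in boundary
        )
        if not extendable:
            maximal.append(KeyPathway(nodes=node_set, exceptions=exc))
    maximal.sort(key=KeyPathway.sort_key)
    return maximal
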