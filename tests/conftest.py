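"""Shared fixtures and the independent brute-force oracle.

The oracle enumerates ALL subsets of the node set, checks validity with its
own machinery (networkx connectivity, direct exception counting), and keeps
the sets with no valid strict superset. It never calls the package's search
code, so agreement between the two is a real cross-check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kpminer import ActivityProfile, IndicatorMatrix, Network, SearchParameters


def profile_of(mapping: dict[str, bool]) -> ActivityProfile:
    return ActivityProfile(active=dict(mapping))


def matrix_of(rows: dict[str, list[int]], name: str = "M1") -> IndicatorMatrix:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"case_{i + 1}" for i in range(frame.shape[1])]
    return IndicatorMatrix(name=name, values=frame)


def naive_maximal_pathways(
    network: Network, profile: ActivityProfile, params: SearchParameters
) -> set[frozenset[str]]:
    """All-subsets reference: valid = connected + at most K exceptions +
    at least one active-state node; maximal = no valid strict superset."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges)

    def state(v: str) -> str:
        if v in params.positive:
            return "active"
        if v in params.negative:
            return "exception"
        return "active" if profile.active[v] else "exception"

    nodes = sorted(network.nodes)
    valid: list[frozenset[str]] = []
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            exc = sum(1 for v in combo if state(v) == "exception")
            if exc > params.k or exc == len(combo):
                continue
            if nx.is_connected(g.subgraph(combo)):
                valid.append(frozenset(combo))
    return {
        s for s in valid
        if not any(s < t for t in valid)
    }


def random_instance(seed: int, n_min: int = 5, n_max: int = 12):
    """Seeded random graph + random activity + random K and node lists."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    names = [f"v{i}" for i in range(n)]
    edges = set()
    for i in range(1, n):  # random spanning tree keeps it connected
        j = int(rng.integers(0, i))
        edges.add((names[j], names[i]))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            a, b = int(min(a, b)), int(max(a, b))
            edges.add((names[a], names[b]))
    network = Network(nodes=names, edges=edges)
    profile = profile_of({v: bool(rng.random() < 0.6) for v in names})
    k = int(rng.integers(0, 3))
    positive = frozenset(v for v in names if rng.random() < 0.1)
    negative = frozenset(v for v in names if v not in positive and rng.random() < 0.1)
    params = SearchParameters(k=k, positive=positive, negative=negative)
    return network, profile, params


@pytest.fixture
def path_abcd() -> Network:
    """The 4-node path A-B-C-D."""
    return Network(nodes="ABCD", edges=[("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def path_profile() -> ActivityProfile:
    """Active A, B, D; C is the lone inactive node on the path."""
    return profile_of({"A": True, "B": True, "C": False, "D": True})


@pytest.fixture
def star_network() -> Network:
    """Hub X with leaves L1..L3."""
    return Network(nodes=["X", "L1", "L2", "L3"], edges=[("X", f"L{i}") for i in (1, 2, 3)])
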