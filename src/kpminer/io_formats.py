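"""Readers and writers for all external file formats.

Networks come in as SIF (Cytoscape's Simple Interaction Format) or two-column
tab-separated edge lists; omics studies come in as TSV indicator matrices
(gene rows, binary case columns); prior-knowledge node lists are plain text.
Results go out as GraphML (one file per key pathway), a JSON summary, and a
two-column node-score TSV loadable as a Cytoscape attribute table.

Node-ID matching across every format is byte-exact: no case folding, no
whitespace normalization beyond field splitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("kpminer")

__all__ = [
    "FormatError",
    "Network",
    "IndicatorMatrix",
    "NodeList",
    "read_network",
    "write_network",
    "read_indicator_matrix",
    "write_indicator_matrix",
    "read_node_list",
    "write_pathways",
    "write_node_scores",
    "read_node_scores",
]


class FormatError(ValueError):
    """Malformed input file (carries file and line context in the message)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class Network:
    """Undirected interaction network over string node IDs.

    Edges are unordered pairs stored once; self-loops and duplicates are
    rejected at construction. Degree-0 nodes are allowed (SIF can declare
    isolated nodes on single-token lines).
    """

    __slots__ = ("nodes", "edges", "adj")

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
            edge_set.add((a, b) if a <= b else (b, a))
        self.adj = adj
        self.nodes = frozenset(adj)
        self.edges = frozenset(edge_set)

    def __contains__(self, node: str) -> bool:
        return node in self.adj

    def __len__(self) -> int:
        return len(self.adj)

    def neighbors(self, node: str) -> set[str]:
        return self.adj[node]

    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self):  # pragma: no cover - identity not used as key
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"Network(n_nodes={len(self.nodes)}, n_edges={len(self.edges)})"

    def is_connected_subset(self, nodes: Iterable[str]) -> bool:
        """True iff the induced subgraph on ``nodes`` is connected and non-empty."""
        node_set = set(nodes)
        if not node_set:
            return False
        start = next(iter(node_set))
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in self.adj[v] & node_set:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return seen == node_set

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass
class IndicatorMatrix:
    """Gene x case binary activity table for one omics study.

    ``values`` is a pandas DataFrame indexed by gene ID with one column per
    case; every cell is 0 or 1 (1 = significantly altered / active in that
    case). The per-study case-exception threshold L is applied to the count
    of 0 entries in a gene's row.
    """

    name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError(f"matrix {self.name!r} has no case columns")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"matrix {self.name!r}: duplicate gene ID {dupes[0]!r}")
        if self.values.columns.has_duplicates:
            raise ValueError(f"matrix {self.name!r}: duplicate case IDs")
        if not self.values.isin([0, 1]).all().all():
            raise ValueError(f"matrix {self.name!r}: values outside {{0,1}}")
        self.values = self.values.astype("int8")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cases(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cases(self) -> int:
        return self.values.shape[1]

    def inactive_counts(self) -> pd.Series:
        """Per-gene count of non-active (0) cases."""
        return (self.values == 0).sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndicatorMatrix):
            return NotImplemented
        return self.name == other.name and self.values.equals(other.values)


@dataclass(frozen=True)
class NodeList:
    """Prior-knowledge node list: ``positive`` entries bypass the exception
    budget, ``negative`` entries always consume it."""

    kind: str  # "positive" | "negative"
    ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in ("positive", "negative"):
            raise ValueError(f"unknown node-list kind {self.kind!r}")


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def _sif_fields(line: str) -> list[str]:
    # SIF allows tab- or whitespace-delimited fields; tabs win when present
    # so that node IDs containing spaces survive in tab-delimited files.
    return line.split("\t") if "\t" in line else line.split()


def read_network(path: str | Path, format: str = "auto") -> Network:
    """Parse an interaction network from SIF or a 2-column edge list.

    The interaction-type column of SIF is ignored: the network is untyped and
    undirected. Duplicate edges collapse, self-loops are dropped (count
    logged), and single-token SIF lines declare isolated nodes.
    """
    path = Path(path)
    if format not in ("sif", "edgelist", "auto"):
        raise ValueError(f"unknown network format {format!r}")
    raw = path.read_text(encoding="utf-8")
    lines = raw.splitlines()
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("#")]
    if not content:
        raise FormatError(f"{path}: empty network file")
    if format == "auto":
        if path.suffix.lower() == ".sif":
            format = "sif"
        else:
            # 2 fields on the first data line -> edge list, otherwise SIF
            format = "edgelist" if len(_sif_fields(content[0][1].strip())) == 2 else "sif"

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    declared = 0

    def add_edge(a: str, b: str) -> None:
        nonlocal self_loops, declared
        declared += 1
        nodes.add(a)
        nodes.add(b)
        if a == b:
            self_loops += 1
            return
        edges.add((a, b) if a <= b else (b, a))

    for lineno, line in content:
        fields = _sif_fields(line.strip())
        if format == "edgelist":
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            add_edge(fields[0], fields[1])
        else:  # sif
            if len(fields) == 1:
                nodes.add(fields[0])
            elif len(fields) == 2:
                raise FormatError(
                    f"{path}:{lineno}: SIF line has 2 fields; expected "
                    "'source interaction target...' or a single node"
                )
            else:
                src = fields[0]
                for target in fields[2:]:
                    add_edge(src, target)

    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    logger.info(
        "%s: parsed %d nodes, %d edges (%d interaction declarations)",
        path, len(nodes), len(edges), declared,
    )
    return Network(nodes=nodes, edges=edges)


def write_network(network: Network, path: str | Path, format: str = "sif") -> None:
    """Write a network as SIF (interaction type ``pp``) or a 2-column edge list."""
    path = Path(path)
    lines: list[str] = []
    if format == "sif":
        linked = {v for e in network.edges for v in e}
        for a, b in sorted(network.edges):
            lines.append(f"{a}\tpp\t{b}")
        for v in sorted(network.nodes - linked):
            lines.append(v)
    elif format == "edgelist":
        if network.nodes - {v for e in network.edges for v in e}:
            raise ValueError("edge-list format cannot represent isolated nodes; use SIF")
        for a, b in sorted(network.edges):
            lines.append(f"{a}\t{b}")
    else:
        raise ValueError(f"unknown network format {format!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# indicator-matrix I/O
# ---------------------------------------------------------------------------


def read_indicator_matrix(
    path: str | Path,
    name: str,
    has_header: bool = False,
    missing_token: str | None = None,
) -> IndicatorMatrix:
    """Read a TSV indicator matrix: first column gene ID, remaining columns 0/1.

    Without a header row, cases are auto-named ``case_1..case_n`` (case
    identity never enters the math; only per-row counts do). A configurable
    ``missing_token`` may map to 0 (non-active); the default is strict {0,1}.
    """
    path = Path(path)
    rows: list[tuple[str, list[int]]] = []
    header: list[str] | None = None
    width: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if has_header and header is None:
                header = fields[1:]
                width = len(fields)
                continue
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} columns, expected {width})"
                )
            gene, cells = fields[0], fields[1:]
            if not cells:
                raise FormatError(f"{path}:{lineno}: no case columns")
            parsed: list[int] = []
            for col, cell in enumerate(cells, start=2):
                if missing_token is not None and cell == missing_token:
                    parsed.append(0)
                elif cell in ("0", "1"):
                    parsed.append(int(cell))
                else:
                    raise FormatError(
                        f"{path}:{lineno}: column {col}: value {cell!r} is not 0/1"
                    )
            rows.append((gene, parsed))
    if not rows:
        raise FormatError(f"{path}: empty indicator matrix")
    genes = [g for g, _ in rows]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise FormatError(f"{path}: duplicate gene ID {g!r}")
        seen.add(g)
    n_cases = len(rows[0][1])
    cases = header if header is not None else [f"case_{i + 1}" for i in range(n_cases)]
    if len(cases) != n_cases:
        raise FormatError(f"{path}: header names {len(cases)} cases but rows have {n_cases}")
    frame = pd.DataFrame([cells for _, cells in rows], index=genes, columns=cases, dtype="int8")
    logger.info("%s: matrix %r with %d genes, %d cases", path, name, len(genes), n_cases)
    return IndicatorMatrix(name=name, values=frame)


def write_indicator_matrix(
    matrix: IndicatorMatrix, path: str | Path, with_header: bool = False
) -> None:
    path = Path(path)
    lines: list[str] = []
    if with_header:
        lines.append("gene\t" + "\t".join(matrix.cases))
    for gene, row in matrix.values.iterrows():
        lines.append(str(gene) + "\t" + "\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# node lists
# ---------------------------------------------------------------------------


def read_node_list(path: str | Path, kind: str) -> NodeList:
    """Read a plain-text node list (one ID per line, ``#`` comments allowed)."""
    path = Path(path)
    ids: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return NodeList(kind=kind, ids=frozenset(ids))


def check_node_lists(
    positive: NodeList | None, negative: NodeList | None, network: Network
) -> tuple[frozenset[str], frozenset[str]]:
    """Validate list disjointness and restrict to network nodes (warning on misses)."""
    pos = positive.ids if positive else frozenset()
    neg = negative.ids if negative else frozenset()
    overlap = pos & neg
    if overlap:
        raise ValueError(
            f"positive and negative lists overlap: {sorted(overlap)[:5]}"
        )
    for kind, ids in (("positive", pos), ("negative", neg)):
        missing = ids - network.nodes
        if missing:
            logger.warning(
                "%s list: %d ID(s) absent from the network (ignored)", kind, len(missing)
            )
    return pos & network.nodes, neg & network.nodes


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------


def _pathway_sort_key(pw) -> tuple[int, tuple[str, ...]]:
    return (-len(pw.nodes), tuple(sorted(pw.nodes)))


def write_pathways(pathways: Sequence, network: Network, out_dir: str | Path) -> list[Path]:
    """Export key pathways: one GraphML per pathway plus a JSON summary.

    Each GraphML holds the induced subgraph with a boolean node attribute
    ``exception``. The JSON lists pathways sorted by descending node count,
    ties broken lexicographically by sorted node IDs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pw in pathways:
        missing = set(pw.nodes) - network.nodes
        if missing:
            raise ValueError(f"pathway node(s) not in network: {sorted(missing)[:5]}")
    ordered = sorted(pathways, key=_pathway_sort_key)
    written: list[Path] = []
    summary = {"pathways": []}
    for rank, pw in enumerate(ordered, start=1):
        g = nx.Graph()
        for v in sorted(pw.nodes):
            g.add_node(v, exception=bool(v in pw.exceptions))
        for a, b in sorted(network.edges):
            if a in pw.nodes and b in pw.nodes:
                g.add_edge(a, b)
        gpath = out_dir / f"pathway_{rank:03d}.graphml"
        nx.write_graphml(g, gpath, named_key_ids=True)
        written.append(gpath)
        summary["pathways"].append(
            {
                "rank": rank,
                "size": len(pw.nodes),
                "n_exceptions": len(pw.exceptions),
                "nodes": sorted(pw.nodes),
                "exceptions": sorted(pw.exceptions),
                "file": gpath.name,
            }
        )
    jpath = out_dir / "pathways.json"
    jpath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(jpath)
    return written


def write_node_scores(scores: Mapping[str, float], path: str | Path) -> None:
    """Write a 2-column ``node_id<TAB>score`` TSV, sorted by node ID.

    Scores must lie in [0,1] and print at 6 decimal places; the file is
    loadable as a Cytoscape node-attribute table for continuous color mapping.
    """
    path = Path(path)
    for node, score in scores.items():
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score for {node!r} outside [0,1]: {score}")
    lines = ["node_id\tscore"]
    for node in sorted(scores):
        lines.append(f"{node}\t{scores[node]:.6f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_node_scores(path: str | Path) -> dict[str, float]:
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if lineno == 1 and line == "node_id\tscore":
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        scores[fields[0]] = float(fields[1])
    return scores
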