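"""Per-node activity from indicator matrices, L thresholds and a boolean formula.

A gene counts as active for one study when its row holds at most L non-active
(zero) cases; L can be given as an absolute count or as a percentage of the
study's cases. Multiple studies are merged either cell-wise (same cohort:
identical case lists, one combined matrix) or, for unconnected cohorts, by
evaluating a boolean formula (AND/OR/XOR tree) over the per-matrix activity
literals. The result is a total activity predicate over the network's node
set, computed once up front; the search algorithms never touch the matrices.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import IndicatorMatrix

logger = logging.getLogger("kpminer")

__all__ = [
    "CaseExceptionSpec",
    "CombinedFormula",
    "ActivityProfile",
    "FormulaError",
    "resolve_case_exceptions",
    "count_inactive_cases",
    "matrix_activity",
    "parse_formula",
    "evaluate_formula",
    "cellwise_combine",
    "compute_activity",
]


# ---------------------------------------------------------------------------
# case-exception thresholds (L)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseExceptionSpec:
    """Maximum number of non-active cases a gene may show and still count as
    active for one study: an absolute count, or a percentage of the cases."""

    mode: str  # "absolute" | "percent"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "percent"):
            raise ValueError(f"unknown case-exception mode {self.mode!r}")
        if self.mode == "absolute":
            if self.value < 0 or int(self.value) != self.value:
                raise ValueError(f"absolute L must be a non-negative integer, got {self.value}")
        else:
            if not (0.0 <= self.value <= 100.0):
                raise ValueError(f"percent L must lie in [0,100], got {self.value}")

    @classmethod
    def parse(cls, text: str) -> "CaseExceptionSpec":
        """Parse ``"39"`` (absolute) or ``"25%"`` (percent of cases)."""
        text = text.strip()
        if text.endswith("%"):
            return cls("percent", float(text[:-1]))
        return cls("absolute", int(text))

    def __str__(self) -> str:
        if self.mode == "percent":
            return f"{self.value:g}%"
        return str(int(self.value))


def resolve_case_exceptions(spec: CaseExceptionSpec, n_cases: int) -> int:
    """Resolve an L spec against a study's case count.

    Percent mode takes the ceiling of the exact fraction (the smallest
    integer number of case exceptions covering the requested share), e.g.
    25% of 155 cases -> 39 and 25% of 291 -> 73. Absolute values larger than
    the case count are clamped with a warning.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if spec.mode == "percent":
        exact = spec.value * n_cases / 100.0
        return math.ceil(exact - 1e-9)
    value = int(spec.value)
    if value > n_cases:
        logger.warning("L=%d exceeds the %d cases; clamping to %d", value, n_cases, n_cases)
        return n_cases
    return value


# ---------------------------------------------------------------------------
# per-matrix activity
# ---------------------------------------------------------------------------


def count_inactive_cases(matrix: IndicatorMatrix, gene: str) -> int:
    """Number of 0 entries in the gene's row; a gene absent from the matrix
    counts every case as non-active (conservative: absence is not signal)."""
    if gene not in matrix.values.index:
        return matrix.n_cases
    return int((matrix.values.loc[gene] == 0).sum())


def matrix_activity(matrix: IndicatorMatrix, l_value: int, genes: Iterable[str]) -> dict[str, bool]:
    """Per-gene activity literal for one study: inactive-case count <= L."""
    if not (0 <= l_value <= matrix.n_cases):
        raise ValueError(f"L={l_value} outside [0, {matrix.n_cases}]")
    counts = matrix.inactive_counts()
    present = {g: bool(c <= l_value) for g, c in counts.items()}
    return {g: present.get(g, matrix.n_cases <= l_value) for g in genes}


# ---------------------------------------------------------------------------
# boolean combination formula
# ---------------------------------------------------------------------------


class FormulaError(ValueError):
    """Malformed combination formula (message carries the token position)."""


@dataclass(frozen=True)
class _Leaf:
    name: str


@dataclass(frozen=True)
class _BinOp:
    op: str  # "AND" | "OR" | "XOR"
    left: "_Leaf | _BinOp"
    right: "_Leaf | _BinOp"


@dataclass(frozen=True)
class CombinedFormula:
    """Boolean expression tree over matrix-name literals.

    Internal nodes are the binary connectors AND, OR, XOR; leaves name
    indicator matrices. The textual form is infix with parentheses, e.g.
    ``(M1 AND M2) OR (M3 AND M4)``; unparenthesized chains associate left.
    """

    root: _Leaf | _BinOp
    text: str = field(compare=False, default="")

    def leaves(self) -> set[str]:
        out: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, _Leaf):
                out.add(node.name)
            else:
                stack.extend((node.left, node.right))
        return out

    def evaluate(self, values: Mapping[str, bool]) -> bool:
        def ev(node) -> bool:
            if isinstance(node, _Leaf):
                try:
                    return bool(values[node.name])
                except KeyError:
                    raise FormulaError(f"no activity literal for matrix {node.name!r}") from None
            a, b = ev(node.left), ev(node.right)
            if node.op == "AND":
                return a and b
            if node.op == "OR":
                return a or b
            return a != b  # XOR

        return ev(self.root)

    def __str__(self) -> str:
        def fmt(node) -> str:
            if isinstance(node, _Leaf):
                return node.name
            return f"({fmt(node.left)} {node.op} {fmt(node.right)})"

        return fmt(self.root)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def parse_formula(text: str, matrix_names: Iterable[str] | None = None) -> CombinedFormula:
    """Parse an infix AND/OR/XOR formula over matrix names.

    All three connectors share one precedence level and associate left:
    ``M1 AND M2 OR M3`` parses as ``((M1 AND M2) OR M3)``. Parentheses
    override. Operator names are case-insensitive; matrix names are not.
    When ``matrix_names`` is given, every leaf must name a supplied matrix
    and every supplied matrix must appear at least once.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def parse_operand():
        nonlocal idx
        tok = peek()
        if tok is None:
            raise FormulaError(f"formula ends unexpectedly at position {len(text)}")
        value, at = tok
        if value == "(":
            idx += 1
            node = parse_chain()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise FormulaError(f"unbalanced parentheses: '(' at position {at} is never closed")
            idx += 1
            return node
        if value == ")":
            raise FormulaError(f"unbalanced parentheses: unexpected ')' at position {at}")
        if value.upper() in ("AND", "OR", "XOR"):
            raise FormulaError(f"expected matrix name at position {at}, got operator {value!r}")
        idx += 1
        return _Leaf(value)

    def parse_chain():
        nonlocal idx
        node = parse_operand()
        while True:
            tok = peek()
            if tok is None or tok[0] == ")":
                return node
            op, at = tok
            if op.upper() not in ("AND", "OR", "XOR"):
                raise FormulaError(f"expected AND/OR/XOR at position {at}, got {op!r}")
            idx += 1
            node = _BinOp(op.upper(), node, parse_operand())

    root = parse_chain()
    if idx != len(tokens):
        value, at = tokens[idx]
        raise FormulaError(f"unbalanced parentheses: unexpected {value!r} at position {at}")
    formula = CombinedFormula(root=root, text=text)
    if matrix_names is not None:
        names = set(matrix_names)
        unknown = formula.leaves() - names
        if unknown:
            raise FormulaError(f"formula names unknown matrix {sorted(unknown)[0]!r}")
        unused = names - formula.leaves()
        if unused:
            raise FormulaError(f"matrix {sorted(unused)[0]!r} never appears in the formula")
    return formula


# ---------------------------------------------------------------------------
# activity profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityProfile:
    """Total activity predicate over the network's node set, derived
    deterministically from the matrices, the resolved L values and the
    combination formula."""

    active: Mapping[str, bool]

    def is_active(self, node: str) -> bool:
        return bool(self.active[node])

    def active_nodes(self) -> frozenset[str]:
        return frozenset(v for v, a in self.active.items() if a)


def evaluate_formula(
    formula: CombinedFormula,
    literals: Mapping[str, Mapping[str, bool]],
    genes: Iterable[str],
) -> ActivityProfile:
    """Evaluate the combination formula per gene over per-matrix literals."""
    missing = formula.leaves() - set(literals)
    if missing:
        raise FormulaError(f"no literals supplied for matrix {sorted(missing)[0]!r}")
    active = {
        g: formula.evaluate({name: lit[g] for name, lit in literals.items()})
        for g in genes
    }
    return ActivityProfile(active=active)


def compute_activity(
    network_nodes: Iterable[str],
    matrices: Mapping[str, IndicatorMatrix],
    l_values: Mapping[str, int],
    formula: CombinedFormula,
) -> ActivityProfile:
    """Full pipeline: per-matrix literals under each resolved L, then the formula.

    The gene universe is the network's node set; genes missing from a matrix
    are inactive there for any L below the case count.
    """
    genes = list(network_nodes)
    literals = {
        name: matrix_activity(matrices[name], l_values[name], genes) for name in matrices
    }
    return evaluate_formula(formula, literals, genes)


# ---------------------------------------------------------------------------
# cell-wise combination (same-cohort studies)
# ---------------------------------------------------------------------------

_CELL_OPS = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
}


def cellwise_combine(m1: IndicatorMatrix, m2: IndicatorMatrix, op: str) -> IndicatorMatrix:
    """Combine two same-cohort matrices cell by cell into one matrix.

    Requires identical case lists (same cases, same order). The gene set is
    the union; a gene absent from one matrix contributes an all-zero row.
    """
    op = op.upper()
    if op not in _CELL_OPS:
        raise ValueError(f"unknown cell-wise operator {op!r}")
    if list(m1.cases) != list(m2.cases):
        raise ValueError(
            "case lists differ between matrices; cell-wise combination requires the "
            "same cohort — use per-matrix L thresholds with a combination formula instead"
        )
    genes = sorted(set(m1.genes) | set(m2.genes))
    a = m1.values.reindex(genes, fill_value=0).astype(bool)
    b = m2.values.reindex(genes, fill_value=0).astype(bool)
    combined = _CELL_OPS[op](a, b).astype("int8")
    return IndicatorMatrix(name=f"({m1.name} {op} {m2.name})", values=combined)
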