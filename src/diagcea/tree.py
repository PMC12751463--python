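"""Typed diagnostic-tree data model.

A diagnostic workflow is modelled as a rooted tree of typed nodes:

* ``decision`` — a clinical judgment point where the next action is chosen
  (carries an expert/consult fee and consult time);
* ``action`` — an executed diagnostic step such as a test or consultation
  (carries the test cost and turnaround time);
* ``result`` — a dichotomous test outcome, positive (1) or negative (0);
* ``exit`` — termination of the diagnostic process.

Edges carry transition probabilities; the outgoing probabilities of every
parent sum to one, so the probabilities of all root-to-leaf paths also sum
to one. A result node routes deterministically (single child, probability
exactly 1). Trees are serialized as JSON with an explicit edge list so that
parameter templates can be patched in place.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import InvalidTreeError, SizeError, TreeFormatError

__all__ = [
    "NODE_KINDS",
    "PROB_TOL",
    "Node",
    "Transition",
    "DiagnosticTree",
    "Violation",
    "validate_tree",
    "enumerate_paths",
    "load_tree",
    "save_tree",
    "random_tree",
]

NODE_KINDS = ("decision", "action", "result", "exit")

#: Absolute tolerance on probability sums (per parent and over all paths).
PROB_TOL = 1e-9

PROVENANCES = (
    "protocol",
    "yield",
    "ai_precision",
    "ai_threshold",
    "empirical",
    "trivial",
)


@dataclass(frozen=True)
class Node:
    """One node of a diagnostic tree.

    Parameters
    ----------
    id:
        Unique string label.
    kind:
        One of ``decision``, ``action``, ``result``, ``exit``.
    base_cost:
        Direct cost attached to the node, in currency units (>= 0).
        Result and exit nodes usually carry no cost.
    turnaround_weeks:
        Calendar time the node adds to the pathway, in weeks (>= 0).
    result_value:
        Dichotomous outcome, 1 (positive) or 0 (negative). Present iff
        ``kind == "result"``.
    ai_flag:
        Marks AI action / AI result nodes in the delegation mode.
    display_name:
        Free-text label for reports.
    """

    id: str
    kind: str
    base_cost: float = 0.0
    turnaround_weeks: float = 0.0
    result_value: int | None = None
    ai_flag: bool = False
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(
                f"node {self.id!r}: unknown node kind {self.kind!r}; "
                f"expected one of {NODE_KINDS}"
            )


@dataclass(frozen=True)
class Transition:
    """A directed edge with its transition probability."""

    parent_id: str
    child_id: str
    probability: float
    provenance: str = "protocol"


@dataclass
class DiagnosticTree:
    """A rooted diagnostic-process tree.

    ``nodes`` maps node id to :class:`Node`; ``transitions`` is the explicit
    edge list. The adjacency structure is computed lazily and cached; trees
    are treated as immutable — transformations return new trees.
    """

    nodes: dict[str, Node]
    transitions: list[Transition]
    root_id: str
    _children: dict[str, list[Transition]] | None = field(
        default=None, repr=False, compare=False
    )
    _parents: dict[str, list[str]] | None = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def build(
        cls,
        nodes: Sequence[Node],
        transitions: Sequence[Transition],
        root_id: str,
    ) -> "DiagnosticTree":
        node_map: dict[str, Node] = {}
        for node in nodes:
            if node.id in node_map:
                raise ValueError(f"duplicate node id {node.id!r}")
            node_map[node.id] = node
        return cls(node_map, list(transitions), root_id)

    # -- adjacency ---------------------------------------------------------

    def _index(self) -> None:
        children: dict[str, list[Transition]] = {nid: [] for nid in self.nodes}
        parents: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for tr in self.transitions:
            if tr.parent_id in children:
                children[tr.parent_id].append(tr)
            if tr.child_id in parents:
                parents[tr.child_id].append(tr.parent_id)
        self._children = children
        self._parents = parents

    def children(self, node_id: str) -> list[Transition]:
        if self._children is None:
            self._index()
        assert self._children is not None
        return self._children[node_id]

    def parents(self, node_id: str) -> list[str]:
        if self._parents is None:
            self._index()
        assert self._parents is not None
        return self._parents[node_id]

    def leaves(self) -> list[str]:
        return [nid for nid in self.nodes if not self.children(nid)]

    def node(self, node_id: str) -> Node:
        return self.nodes[node_id]

    def copy(self) -> "DiagnosticTree":
        return DiagnosticTree(dict(self.nodes), list(self.transitions), self.root_id)

    def with_node(self, node: Node) -> "DiagnosticTree":
        """Return a new tree with one node replaced (same id)."""
        nodes = dict(self.nodes)
        nodes[node.id] = node
        return DiagnosticTree(nodes, list(self.transitions), self.root_id)


@dataclass(frozen=True)
class Violation:
    """One violated tree invariant, naming the offending node or edge."""

    code: str
    subject: str
    message: str


def _violation(code: str, subject: str, message: str) -> Violation:
    return Violation(code, subject, f"{subject}: {message}")


def validate_tree(tree: DiagnosticTree) -> list[Violation]:
    """Check every structural invariant; return one record per violation.

    An empty list means the tree is valid. Checks: root membership, orphan
    transitions, duplicate edges, multiple parents, cycles, unreachable
    nodes, probability ranges and per-parent sums, deterministic routing of
    result nodes, non-exit leaves, exits with children, negative costs or
    turnarounds, result-value presence and dichotomy, and the total
    root-to-leaf path probability.
    """
    out: list[Violation] = []

    if tree.root_id not in tree.nodes:
        out.append(_violation("missing-root", tree.root_id, "root id is not a node"))
        return out

    children: dict[str, list[Transition]] = {nid: [] for nid in tree.nodes}
    parent_count: dict[str, int] = {nid: 0 for nid in tree.nodes}
    seen_edges: set[tuple[str, str]] = set()
    orphan = False
    for tr in tree.transitions:
        edge = f"edge {tr.parent_id!r}->{tr.child_id!r}"
        if tr.parent_id not in tree.nodes or tr.child_id not in tree.nodes:
            out.append(_violation("orphan-transition", edge, "references unknown node"))
            orphan = True
            continue
        if (tr.parent_id, tr.child_id) in seen_edges:
            out.append(_violation("duplicate-edge", edge, "edge listed twice"))
        seen_edges.add((tr.parent_id, tr.child_id))
        if not (0.0 <= tr.probability <= 1.0) or not math.isfinite(tr.probability):
            out.append(
                _violation(
                    "probability-range",
                    edge,
                    f"probability {tr.probability!r} outside [0, 1]",
                )
            )
        if tr.provenance not in PROVENANCES:
            out.append(
                _violation(
                    "unknown-provenance", edge, f"unknown provenance {tr.provenance!r}"
                )
            )
        children[tr.parent_id].append(tr)
        parent_count[tr.child_id] += 1

    for nid, count in parent_count.items():
        if nid == tree.root_id:
            if count:
                out.append(_violation("root-parent", nid, "root node has a parent"))
        elif count > 1:
            out.append(_violation("multiple-parents", nid, f"{count} parents"))

    # Node-level attribute checks.
    for nid, node in tree.nodes.items():
        if node.base_cost < 0:
            out.append(_violation("negative-cost", nid, f"base_cost {node.base_cost}"))
        if node.turnaround_weeks < 0:
            out.append(
                _violation(
                    "negative-turnaround", nid, f"turnaround {node.turnaround_weeks}"
                )
            )
        if node.kind == "result":
            if node.result_value is None:
                out.append(_violation("missing-result-value", nid, "result node has no result_value"))
            elif node.result_value not in (0, 1):
                out.append(
                    _violation(
                        "continuous-result",
                        nid,
                        f"result_value {node.result_value!r} is not dichotomous; "
                        "continuous test results are not supported — encode a "
                        "quantitative test as a thresholded 0/1 result",
                    )
                )
        elif node.result_value is not None:
            out.append(
                _violation(
                    "spurious-result-value",
                    nid,
                    f"{node.kind} node carries a result_value",
                )
            )

    # Probability sums and kind-specific branching rules.
    for nid, outgoing in children.items():
        node = tree.nodes[nid]
        if not outgoing:
            if node.kind != "exit":
                out.append(_violation("non-exit-leaf", nid, f"leaf has kind {node.kind!r}"))
            continue
        if node.kind == "exit":
            out.append(_violation("exit-with-children", nid, "exit node has children"))
        total = sum(tr.probability for tr in outgoing)
        if abs(total - 1.0) > PROB_TOL:
            out.append(
                _violation(
                    "probability-sum",
                    nid,
                    f"outgoing probabilities sum to {total!r}, not 1",
                )
            )
        if node.kind == "result":
            if len(outgoing) != 1:
                out.append(
                    _violation("result-branching", nid, f"result node has {len(outgoing)} children")
                )
            elif outgoing[0].probability != 1.0:
                out.append(
                    _violation(
                        "result-trivial-probability",
                        nid,
                        "transition out of a result node must have probability exactly 1",
                    )
                )

    if orphan:
        return out

    # Reachability and acyclicity from the root.
    # Iterative DFS; with at most one parent per node a cycle (or any
    # diamond) must re-enter an already-visited node.
    visited: set[str] = set()
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        if nid in visited:
            out.append(_violation("cycle", nid, "node reachable twice from the root"))
            continue
        visited.add(nid)
        for tr in children[nid]:
            stack.append(tr.child_id)
    unreachable = set(tree.nodes) - visited
    for nid in sorted(unreachable):
        out.append(_violation("unreachable", nid, "not reachable from the root"))

    # Total path probability (only meaningful when everything above holds).
    if not out:
        total = sum(p for _, p in _iter_paths(tree, children))
        if abs(total - 1.0) > PROB_TOL:
            out.append(
                _violation(
                    "path-probability-sum",
                    tree.root_id,
                    f"root-to-leaf path probabilities sum to {total!r}, not 1",
                )
            )
    return out


def _iter_paths(
    tree: DiagnosticTree,
    children: Mapping[str, list[Transition]] | None = None,
) -> Iterator[tuple[list[str], float]]:
    if children is None:
        children = {nid: tree.children(nid) for nid in tree.nodes}
    stack: list[tuple[str, float, list[str]]] = [(tree.root_id, 1.0, [tree.root_id])]
    while stack:
        nid, prob, path = stack.pop()
        outgoing = children[nid]
        if not outgoing:
            yield path, prob
            continue
        for tr in outgoing:
            stack.append((tr.child_id, prob * tr.probability, path + [tr.child_id]))


def enumerate_paths(
    tree: DiagnosticTree, *, validate: bool = True, max_paths: int = 1_000_000
) -> list[tuple[list[str], float]]:
    """Enumerate all root-to-leaf paths with their probabilities.

    Each entry is ``(node-id sequence, product of edge probabilities)``;
    over a valid tree the probabilities sum to one. Raises
    :class:`InvalidTreeError` when ``validate`` is set and the tree is
    invalid, and :class:`SizeError` beyond ``max_paths`` leaves.
    """
    if validate:
        violations = validate_tree(tree)
        if violations:
            raise InvalidTreeError(violations)
    paths: list[tuple[list[str], float]] = []
    for path, prob in _iter_paths(tree):
        paths.append((path, prob))
        if len(paths) > max_paths:
            raise SizeError(f"more than {max_paths} root-to-leaf paths")
    # DFS order depends on edge-list order via a stack; present paths in
    # stable, reader-friendly order (as listed in the edge list).
    paths.reverse()
    return paths


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------
#
# Schema (all weeks; conversion to years happens inside effectiveness code):
# {
#   "root": "<node id>",
#   "nodes": [{"id", "kind", "ai"?, "cost"?, "turnaround_weeks"?,
#              "result_value"?, "name"?}, ...],
#   "edges": [{"from", "to", "p", "provenance"?}, ...]
# }


def _require(mapping: object, key: str, types: tuple, path: str):
    if not isinstance(mapping, dict):
        raise TreeFormatError(f"{path}: expected an object, got {type(mapping).__name__}")
    if key not in mapping:
        raise TreeFormatError(f"{path}.{key}: missing required field")
    value = mapping[key]
    if not isinstance(value, types) or isinstance(value, bool) and bool not in types:
        expected = "/".join(t.__name__ for t in types)
        raise TreeFormatError(
            f"{path}.{key}: expected {expected}, got {type(value).__name__}"
        )
    return value


def load_tree(text: str) -> DiagnosticTree:
    """Parse a tree from JSON text; schema violations raise TreeFormatError.

    The parsed tree is validated; structural violations raise
    :class:`InvalidTreeError` (use :func:`validate_tree` directly to inspect
    them without raising).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TreeFormatError(f"$: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise TreeFormatError("$: top level must be an object")
    root = _require(doc, "root", (str,), "$")
    raw_nodes = _require(doc, "nodes", (list,), "$")
    raw_edges = _require(doc, "edges", (list,), "$")

    nodes: list[Node] = []
    for i, raw in enumerate(raw_nodes):
        path = f"$.nodes[{i}]"
        nid = _require(raw, "id", (str,), path[2:])
        kind = _require(raw, "kind", (str,), path[2:])
        if kind not in NODE_KINDS:
            raise TreeFormatError(
                f"nodes[{i}].kind: unknown node kind {kind!r}; expected one of {NODE_KINDS}"
            )
        cost = raw.get("cost", 0.0)
        if not isinstance(cost, (int, float)) or isinstance(cost, bool):
            raise TreeFormatError(f"nodes[{i}].cost: expected a number")
        tat = raw.get("turnaround_weeks", 0.0)
        if not isinstance(tat, (int, float)) or isinstance(tat, bool):
            raise TreeFormatError(f"nodes[{i}].turnaround_weeks: expected a number")
        result_value = raw.get("result_value")
        if result_value is not None and (
            not isinstance(result_value, int) or isinstance(result_value, bool)
        ):
            raise TreeFormatError(
                f"nodes[{i}].result_value: expected an integer 0/1 "
                "(continuous results are not supported)"
            )
        ai = raw.get("ai", False)
        if not isinstance(ai, bool):
            raise TreeFormatError(f"nodes[{i}].ai: expected a boolean")
        name = raw.get("name", "")
        if not isinstance(name, str):
            raise TreeFormatError(f"nodes[{i}].name: expected a string")
        nodes.append(
            Node(
                id=nid,
                kind=kind,
                base_cost=float(cost),
                turnaround_weeks=float(tat),
                result_value=result_value,
                ai_flag=ai,
                display_name=name,
            )
        )

    edges: list[Transition] = []
    for i, raw in enumerate(raw_edges):
        parent = _require(raw, "from", (str,), f"edges[{i}]")
        child = _require(raw, "to", (str,), f"edges[{i}]")
        p = _require(raw, "p", (int, float), f"edges[{i}]")
        provenance = raw.get("provenance", "protocol")
        if provenance not in PROVENANCES:
            raise TreeFormatError(
                f"edges[{i}].provenance: unknown provenance {provenance!r}"
            )
        edges.append(Transition(parent, child, float(p), provenance))

    try:
        tree = DiagnosticTree.build(nodes, edges, root)
    except ValueError as exc:
        raise TreeFormatError(f"nodes: {exc}") from exc
    violations = validate_tree(tree)
    if violations:
        raise InvalidTreeError(violations)
    return tree


def save_tree(tree: DiagnosticTree) -> str:
    """Serialize a tree to canonical JSON (keys sorted, defaults omitted)."""
    raw_nodes = []
    for nid in sorted(tree.nodes):
        node = tree.nodes[nid]
        raw: dict = {"id": node.id, "kind": node.kind}
        if node.base_cost:
            raw["cost"] = node.base_cost
        if node.turnaround_weeks:
            raw["turnaround_weeks"] = node.turnaround_weeks
        if node.result_value is not None:
            raw["result_value"] = node.result_value
        if node.ai_flag:
            raw["ai"] = True
        if node.display_name:
            raw["name"] = node.display_name
        raw_nodes.append(raw)
    raw_edges = [
        {
            "from": tr.parent_id,
            "to": tr.child_id,
            "p": tr.probability,
            **({"provenance": tr.provenance} if tr.provenance != "protocol" else {}),
        }
        for tr in tree.transitions
    ]
    doc = {"root": tree.root_id, "nodes": raw_nodes, "edges": raw_edges}
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# Random trees (property-test fixture generator)
# ---------------------------------------------------------------------------


def random_tree(
    depth: int, branching: int = 3, seed: int | np.random.Generator = 0
) -> DiagnosticTree:
    """Generate a valid random diagnostic tree, deterministic per seed.

    ``depth`` counts decision→action→result cycles plus the terminal exits:
    ``depth=1`` is a single exit node; each additional level adds one cycle.
    Decision fan-out is uniform on 1..``branching``; decision→action
    probabilities are normalized uniform draws, action→result splits are a
    random yield (positive) and its complement.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    nodes: list[Node] = []
    edges: list[Transition] = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter}"

    def make_exit() -> str:
        nid = next_id("x")
        nodes.append(Node(nid, "exit"))
        return nid

    def make_decision(levels_left: int) -> str:
        if levels_left <= 0:
            return make_exit()
        did = next_id("d")
        nodes.append(
            Node(
                did,
                "decision",
                base_cost=float(rng.uniform(50, 250)),
                turnaround_weeks=float(rng.uniform(0, 4)),
            )
        )
        k = int(rng.integers(1, branching + 1))
        weights = rng.uniform(0.05, 1.0, size=k)
        probs = weights / weights.sum()
        # Renormalize exactly so the sum is 1 to machine precision.
        probs[-1] = 1.0 - probs[:-1].sum()
        for p in probs:
            aid = next_id("a")
            nodes.append(
                Node(
                    aid,
                    "action",
                    base_cost=float(rng.uniform(100, 5000)),
                    turnaround_weeks=float(rng.uniform(0, 8)),
                )
            )
            edges.append(Transition(did, aid, float(p), "empirical"))
            yield_p = float(rng.uniform(0.05, 0.95))
            pos = next_id("r")
            neg = next_id("r")
            nodes.append(Node(pos, "result", result_value=1))
            nodes.append(Node(neg, "result", result_value=0))
            edges.append(Transition(aid, pos, yield_p, "yield"))
            edges.append(Transition(aid, neg, 1.0 - yield_p, "yield"))
            # Positive results exit; negative results may continue.
            pos_exit = make_exit()
            edges.append(Transition(pos, pos_exit, 1.0, "trivial"))
            child = make_decision(levels_left - 1)
            edges.append(Transition(neg, child, 1.0, "trivial"))
        return did

    root = make_decision(depth - 1)
    return DiagnosticTree.build(nodes, edges, root)
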