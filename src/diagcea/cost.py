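"""Expected-cost computation over a diagnostic tree.

The accumulated expected cost at a node is its own base cost plus the
probability-weighted expected costs of its children:

    E(C_i+) = C_i                                   if n_i is a leaf
    E(C_i+) = C_i + sum_j P_ij * E(C_j+)            otherwise

A single post-order pass from the leaves to the root evaluates this in
O(N) — each node is visited exactly once. The root value is the expected
total cost of the whole diagnostic process. An independent brute-force
oracle (path enumeration) is provided for testing.
"""

from __future__ import annotations

from .errors import InvalidTreeError, SizeError
from .tree import DiagnosticTree, enumerate_paths, validate_tree

__all__ = ["expected_cost", "expected_cost_bruteforce"]


def expected_cost(
    tree: DiagnosticTree,
    *,
    validate: bool = True,
    visit_log: list[str] | None = None,
) -> dict[str, float]:
    """Accumulated expected cost at every node (post-order rollback).

    Returns a mapping node id -> E(C_i+) covering every node, so callers
    can annotate the whole tree; the root entry is the expected total cost
    of the process. The input tree is never mutated.

    Parameters
    ----------
    validate:
        Run :func:`validate_tree` first and raise on violations. Builders
        that construct trees programmatically may skip this for speed.
    visit_log:
        If given, node ids are appended in evaluation order — one entry per
        node, which operationalizes the linear-time guarantee.
    """
    if validate:
        violations = validate_tree(tree)
        if violations:
            raise InvalidTreeError(violations)

    # Iterative post-order traversal (explicit stack: no recursion limit on
    # deep trees). Children are fully evaluated before their parent.
    costs: dict[str, float] = {}
    stack: list[tuple[str, bool]] = [(tree.root_id, False)]
    while stack:
        nid, expanded = stack.pop()
        if expanded:
            node = tree.nodes[nid]
            total = node.base_cost
            for tr in tree.children(nid):
                total += tr.probability * costs[tr.child_id]
            costs[nid] = total
            if visit_log is not None:
                visit_log.append(nid)
            continue
        stack.append((nid, True))
        for tr in tree.children(nid):
            stack.append((tr.child_id, False))
    return costs


def expected_cost_bruteforce(
    tree: DiagnosticTree, *, validate: bool = True, max_paths: int = 200_000
) -> float:
    """Root expected cost by exhaustive path enumeration (testing oracle).

    Sums, over every root-to-leaf path, the path probability times the sum
    of node base costs along the path. Intended for small trees; raises
    :class:`SizeError` beyond ``max_paths`` paths. Agrees with
    :func:`expected_cost` at the root to floating-point accuracy.
    """
    paths = enumerate_paths(tree, validate=validate, max_paths=max_paths)
    total = 0.0
    for path, prob in paths:
        path_cost = sum(tree.nodes[nid].base_cost for nid in path)
        total += prob * path_cost
    return total
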