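"""AI-delegation transform for diagnostic trees.

In the expert-alone mode, a decision node is the point where a clinician
chooses the next action. Under AI delegation, that decision point is
replaced by an AI action node whose prediction score ``r`` is compared to a
preset threshold ``r*``:

* ``r >= r*`` — the favoured action is ordered automatically. No decision
  fee is incurred anywhere on this branch (test ordering needs no human
  intervention), and the automated test's positive-result probability
  becomes the AI's precision P(true positive | predicted positive).
* ``r < r*`` — the case falls back to an expert decision over a configured
  set of fallback actions, identical in cost and structure to the
  expert-alone mode; downstream yields there are untouched (assumed
  independent of AI performance).

At the population level the branch probability is P(r >= r*) in (0, 1);
for a single patient the score is a fixed number, so the branch probability
is exactly 0 or 1. An empty fallback set expresses the *take-over* pattern,
where a negative AI prediction simply concludes the process at an exit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidTreeError, ModelingError
from .tree import DiagnosticTree, Node, Transition, validate_tree

__all__ = ["AiSpec", "ai_branch_probability", "delegate"]


@dataclass(frozen=True)
class AiSpec:
    """Parameters of one AI decision-support model.

    ``precision`` is P(condition truly positive | AI routes to the test and
    the test reports positive) — the transition probability of the automated
    action's positive result. ``population_rate`` is P(r >= r*) across a
    population; ``patient_score`` is a single patient's fixed prediction
    score, which dichotomizes the branch. AI prediction itself is assumed
    free and instantaneous by default (overridable).
    """

    threshold: float
    precision: float
    population_rate: float | None = None
    patient_score: float | None = None
    turnaround_weeks: float = 0.0
    cost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("threshold", "precision"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_rate is not None and not 0.0 <= self.population_rate <= 1.0:
            raise ValueError(
                f"population_rate must be in [0, 1], got {self.population_rate}"
            )
        if self.cost < 0 or self.turnaround_weeks < 0:
            raise ValueError("cost and turnaround_weeks must be >= 0")


def ai_branch_probability(spec: AiSpec, mode: str = "population") -> float:
    """Probability of the automated (``r >= r*``) branch.

    ``population`` mode returns the population rate P(r >= r*); ``patient``
    mode compares the patient's fixed score to the threshold and returns
    exactly 0.0 or 1.0. In patient mode a fractional ``population_rate``
    cannot stand in for the indicator.
    """
    if mode == "population":
        if spec.population_rate is None:
            raise ValueError("population mode requires population_rate")
        return spec.population_rate
    if mode == "patient":
        if spec.patient_score is not None:
            return 1.0 if spec.patient_score >= spec.threshold else 0.0
        if spec.population_rate in (0.0, 1.0):
            return float(spec.population_rate)
        raise ValueError(
            "patient mode needs a patient_score (or a 0/1 indicator); got "
            f"population_rate={spec.population_rate!r}"
        )
    raise ValueError(f"unknown mode {mode!r}; expected 'population' or 'patient'")


def _subtree_ids(tree: DiagnosticTree, root: str) -> set[str]:
    seen = {root}
    stack = [root]
    while stack:
        nid = stack.pop()
        for tr in tree.children(nid):
            if tr.child_id not in seen:
                seen.add(tr.child_id)
                stack.append(tr.child_id)
    return seen


def delegate(
    tree: DiagnosticTree,
    decision_node_id: str,
    spec: AiSpec,
    automated_action_id: str,
    fallback_action_ids: tuple[str, ...] | list[str] = (),
    *,
    mode: str = "population",
    automate_downstream_decisions: bool = True,
) -> DiagnosticTree:
    """Replace an expert decision node by the AI-delegation structure.

    Returns a new tree in which ``decision_node_id`` is replaced by an AI
    action node (id ``<decision>_ai``) with two AI result children: the
    high branch (``r >= r*``, id ``<decision>_hi``) routes straight to
    ``automated_action_id`` whose positive-result probability is set to
    ``spec.precision``; the low branch (``<decision>_lo``) leads to a copy
    of the expert decision restricted to ``fallback_action_ids`` (their
    subtrees are untouched), or to a plain exit when the fallback set is
    empty (take-over mode). Children of the original decision that are
    neither automated nor fallback are dropped with their subtrees.

    With ``automate_downstream_decisions`` (the default) every decision
    node inside the automated subtree is stripped of its fee and consult
    time — the whole branch runs without human intervention.
    """
    if decision_node_id not in tree.nodes:
        raise ModelingError(f"no node {decision_node_id!r} in tree")
    decision = tree.nodes[decision_node_id]
    if decision.kind != "decision":
        raise ModelingError(
            f"node {decision_node_id!r} has kind {decision.kind!r}; only decision "
            "nodes can be delegated"
        )
    child_ids = [tr.child_id for tr in tree.children(decision_node_id)]
    if automated_action_id not in child_ids:
        raise ModelingError(
            f"automated action {automated_action_id!r} is not a child of "
            f"decision {decision_node_id!r}"
        )
    for fid in fallback_action_ids:
        if fid not in child_ids:
            raise ModelingError(
                f"fallback action {fid!r} is not a child of decision "
                f"{decision_node_id!r}"
            )
    if automated_action_id in fallback_action_ids:
        raise ModelingError("automated action cannot also be a fallback action")

    q = ai_branch_probability(spec, mode)

    # Children of the decision to drop entirely (not automated, not fallback).
    keep = {automated_action_id, *fallback_action_ids}
    dropped: set[str] = set()
    for tr in tree.children(decision_node_id):
        if tr.child_id not in keep:
            dropped |= _subtree_ids(tree, tr.child_id)

    ai_id = f"{decision_node_id}_ai"
    hi_id = f"{decision_node_id}_hi"
    lo_id = f"{decision_node_id}_lo"
    expert_id = f"{decision_node_id}_expert"
    exit_id = f"{decision_node_id}_exit"
    for new_id in (ai_id, hi_id, lo_id, expert_id, exit_id):
        if new_id in tree.nodes:
            raise ModelingError(f"generated node id {new_id!r} already in tree")

    nodes: dict[str, Node] = {
        nid: n
        for nid, n in tree.nodes.items()
        if nid != decision_node_id and nid not in dropped
    }
    nodes[ai_id] = Node(
        ai_id,
        "action",
        base_cost=spec.cost,
        turnaround_weeks=spec.turnaround_weeks,
        ai_flag=True,
        display_name="AI prediction",
    )
    nodes[hi_id] = Node(
        hi_id, "result", result_value=1, ai_flag=True, display_name="r >= r*"
    )
    nodes[lo_id] = Node(
        lo_id, "result", result_value=0, ai_flag=True, display_name="r < r*"
    )

    automated_ids = _subtree_ids(tree, automated_action_id)
    if automate_downstream_decisions:
        for nid in automated_ids:
            node = nodes.get(nid)
            if node is not None and node.kind == "decision":
                nodes[nid] = replace(node, base_cost=0.0, turnaround_weeks=0.0)

    transitions: list[Transition] = []
    fallback_probs: dict[str, float] = {}
    for tr in tree.transitions:
        if tr.parent_id == decision_node_id:
            if tr.child_id in fallback_action_ids:
                fallback_probs[tr.child_id] = tr.probability
            continue  # decision's outgoing edges are rebuilt below
        if tr.child_id == decision_node_id:
            transitions.append(replace(tr, child_id=ai_id))
            continue
        if tr.parent_id in dropped or tr.child_id in dropped:
            continue
        # Automated action: its positive-result probability becomes the AI
        # precision; the negative result takes the complement.
        if (
            tr.parent_id == automated_action_id
            and nodes[tr.child_id].kind == "result"
        ):
            value = nodes[tr.child_id].result_value
            p = spec.precision if value == 1 else 1.0 - spec.precision
            transitions.append(replace(tr, probability=p, provenance="ai_precision"))
            continue
        transitions.append(tr)

    transitions.append(Transition(ai_id, hi_id, q, "ai_threshold"))
    transitions.append(Transition(ai_id, lo_id, 1.0 - q, "ai_threshold"))
    transitions.append(Transition(hi_id, automated_action_id, 1.0, "trivial"))

    if fallback_action_ids:
        # The expert decision on the low branch mirrors the original node.
        nodes[expert_id] = replace(decision, id=expert_id)
        transitions.append(Transition(lo_id, expert_id, 1.0, "trivial"))
        total = sum(fallback_probs.get(fid, 0.0) for fid in fallback_action_ids)
        for fid in fallback_action_ids:
            if total > 0:
                p = fallback_probs.get(fid, 0.0) / total
            else:
                p = 1.0 / len(fallback_action_ids)
            transitions.append(Transition(expert_id, fid, p, "protocol"))
    else:
        nodes[exit_id] = Node(exit_id, "exit", display_name="AI concludes process")
        transitions.append(Transition(lo_id, exit_id, 1.0, "trivial"))

    root = ai_id if tree.root_id == decision_node_id else tree.root_id
    new_tree = DiagnosticTree(nodes, transitions, root)
    violations = validate_tree(new_tree)
    if violations:
        raise InvalidTreeError(violations)
    return new_tree
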