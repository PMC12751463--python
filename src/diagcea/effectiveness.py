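"""Effectiveness: outcome states, predictive values, QALYs, cost per QALY.

Every root-to-leaf pathway of a diagnostic tree terminates in an *outcome
state*: the final dichotomous result (positive/negative), the cumulative
turnaround time TAT (weeks on file, converted to years here), and the path
probability. The quality-adjusted life years accrued over a horizon of
``x`` years are

    QALY_i(x) = TAT_i * U(S_0) + (x - TAT_i) * E[U(S_i)]

where ``U(S_0)`` is the utility of the initial undiagnosed state and the
expected utility of the outcome state weights the true/false diagnosis
cases by the predictive values of the test that produced the final result:

    E[U(S_i)] = PPV * U_TP + (1 - PPV) * U_FP     for a positive result
    E[U(S_i)] = NPV * U_TN + (1 - NPV) * U_FN     for a negative result

PPV and NPV derive from the final test's sensitivity/specificity and the
disease prevalence. Multi-test pathways use the LAST test's accuracy only;
composing accuracy across tiers is out of scope. AI classifiers whose
predictive values are known directly (e.g. a published precision) enter the
registry as :class:`PredictiveValues` instead of sensitivity/specificity.
The expected QALY of a strategy is the probability-weighted average across
its outcome states, and cost per QALY is the cost-effectiveness metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .cost import expected_cost
from .errors import HorizonError, InvalidTreeError, ModelingError
from .tree import DiagnosticTree, enumerate_paths, validate_tree

__all__ = [
    "WEEKS_PER_YEAR",
    "TestPerformance",
    "PredictiveValues",
    "UtilityWeights",
    "CeaConfig",
    "OutcomeState",
    "CeaResult",
    "ppv",
    "npv",
    "outcome_states",
    "expected_utility",
    "qaly",
    "expected_qaly",
    "cost_per_qaly",
    "evaluate",
    "adjust_for_inflation",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity (and optional yield) of one diagnostic test."""

    sensitivity: float
    specificity: float
    diagnostic_yield: float | None = None

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.diagnostic_yield is not None and not 0.0 <= self.diagnostic_yield <= 1.0:
            raise ValueError(f"diagnostic_yield must be in [0, 1], got {self.diagnostic_yield}")


@dataclass(frozen=True)
class PredictiveValues:
    """Directly specified PPV/NPV, bypassing the prevalence formula.

    Used for classifiers whose precision (PPV) is published without an
    underlying sensitivity/specificity pair, and for gold-standard tests
    (``ppv = npv = 1``). Either value may be omitted when the corresponding
    branch never terminates a pathway.
    """

    ppv: float | None = None
    npv: float | None = None

    def __post_init__(self) -> None:
        for name in ("ppv", "npv"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


PerformanceLike = Union[TestPerformance, PredictiveValues]


@dataclass(frozen=True)
class UtilityWeights:
    """Utility weights for diagnostic outcome states.

    ``u_tp``, ``u_tn``, ``u_fp`` lie in [0, 1] with ``u_tp > u_fp``; a
    false negative may be scored worse than death (``u_fn`` in [-1, 0]).
    ``u_undiagnosed`` is the utility of the initial undiagnosed state
    U(S_0), applied during the turnaround period.
    """

    u_tp: float
    u_tn: float
    u_fp: float
    u_fn: float
    u_undiagnosed: float

    def __post_init__(self) -> None:
        for name in ("u_tp", "u_tn", "u_fp", "u_undiagnosed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.u_fn <= 0.0:
            raise ValueError(f"u_fn must be in [-1, 0], got {self.u_fn}")
        if not self.u_tp > self.u_fp:
            raise ValueError(
                f"u_tp ({self.u_tp}) must exceed u_fp ({self.u_fp})"
            )


@dataclass(frozen=True)
class CeaConfig:
    """Evaluation settings for a cost-effectiveness analysis.

    ``ratio_mode`` selects how Monte Carlo replicates are aggregated into a
    cost-per-QALY summary: ``per_replicate`` (each replicate's own ratio is
    summarized — the default) or ``of_expectations`` (mean cost divided by
    mean QALY).
    """

    utilities: UtilityWeights
    prevalence: float
    horizon_years: float = 1.0
    ratio_mode: str = "per_replicate"

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.ratio_mode not in ("per_replicate", "of_expectations"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")


@dataclass(frozen=True)
class OutcomeState:
    """Terminal state of one diagnostic pathway.

    ``outcome`` is the result value of the last result node before the
    exit (None when the exit's utility is supplied directly by an
    override); ``performance`` is the accuracy of the test/classifier that
    produced it; ``utility_override`` short-circuits the predictive-value
    weighting with an explicit expected utility.
    """

    exit_node_id: str
    outcome: int | None
    tat_years: float
    path_probability: float
    terminal_action_id: str | None = None
    performance: PerformanceLike | None = None
    utility_override: float | None = None


def ppv(perf: TestPerformance, prevalence: float) -> float:
    """Positive predictive value from sensitivity, specificity, prevalence."""
    if isinstance(perf, PredictiveValues):
        if perf.ppv is None:
            raise ModelingError("PredictiveValues has no ppv set")
        return perf.ppv
    se, sp, p = perf.sensitivity, perf.specificity, prevalence
    denom = se * p + (1.0 - sp) * (1.0 - p)
    if denom <= 0.0:
        raise ModelingError(
            "PPV undefined: the test never returns a positive result "
            f"(Se={se}, Sp={sp}, p={p})"
        )
    return se * p / denom


def npv(perf: TestPerformance, prevalence: float) -> float:
    """Negative predictive value from sensitivity, specificity, prevalence."""
    if isinstance(perf, PredictiveValues):
        if perf.npv is None:
            raise ModelingError("PredictiveValues has no npv set")
        return perf.npv
    se, sp, p = perf.sensitivity, perf.specificity, prevalence
    denom = sp * (1.0 - p) + (1.0 - se) * p
    if denom <= 0.0:
        raise ModelingError(
            "NPV undefined: the test never returns a negative result "
            f"(Se={se}, Sp={sp}, p={p})"
        )
    return sp * (1.0 - p) / denom


def outcome_states(
    tree: DiagnosticTree,
    perf_registry: Mapping[str, PerformanceLike],
    *,
    overrides: Mapping[str, float] | None = None,
    validate: bool = True,
) -> list[OutcomeState]:
    """Extract one outcome state per exit node of a valid tree.

    ``perf_registry`` maps the id of each *action* node whose results can
    terminate a pathway to its :class:`TestPerformance` (or
    :class:`PredictiveValues`). The outcome of a pathway is the result
    value of the last result node before the exit, and its accuracy is that
    result's parent action. TAT sums the turnaround of every node on the
    pathway (decision consult time included; result/exit nodes contribute
    their own turnaround, normally zero), converted weeks -> years.

    ``overrides`` maps exit node ids to an explicit expected utility for
    pathways whose outcome is not test-like — e.g. an exit with no result
    node among its ancestors, which otherwise raises
    :class:`ModelingError` ("exit without diagnosis").
    """
    overrides = overrides or {}
    paths = enumerate_paths(tree, validate=validate)
    states: list[OutcomeState] = []
    for path, prob in paths:
        exit_id = path[-1]
        tat_weeks = sum(tree.nodes[nid].turnaround_weeks for nid in path)
        last_result: str | None = None
        for nid in path:
            if tree.nodes[nid].kind == "result":
                last_result = nid
        if exit_id in overrides:
            states.append(
                OutcomeState(
                    exit_node_id=exit_id,
                    outcome=(
                        tree.nodes[last_result].result_value
                        if last_result is not None
                        else None
                    ),
                    tat_years=tat_weeks / WEEKS_PER_YEAR,
                    path_probability=prob,
                    terminal_action_id=None,
                    performance=None,
                    utility_override=float(overrides[exit_id]),
                )
            )
            continue
        if last_result is None:
            raise ModelingError(
                f"exit node {exit_id!r} has no result node among its ancestors; "
                "supply an explicit outcome utility for it via overrides"
            )
        parent_action = tree.parents(last_result)[0]
        perf = perf_registry.get(parent_action)
        if perf is None:
            raise ModelingError(
                f"no test performance registered for action node {parent_action!r} "
                f"(terminal result of exit {exit_id!r})"
            )
        states.append(
            OutcomeState(
                exit_node_id=exit_id,
                outcome=tree.nodes[last_result].result_value,
                tat_years=tat_weeks / WEEKS_PER_YEAR,
                path_probability=prob,
                terminal_action_id=parent_action,
                performance=perf,
            )
        )
    return states


def expected_utility(
    state: OutcomeState, prevalence: float, utilities: UtilityWeights
) -> float:
    """Expected utility of an outcome state.

    Positive outcomes weight U_TP/U_FP by PPV; negative outcomes weight
    U_TN/U_FN by NPV. A ``utility_override`` on the state wins outright.
    """
    if state.utility_override is not None:
        return state.utility_override
    if state.performance is None:
        raise ModelingError(
            f"outcome state at exit {state.exit_node_id!r} has no terminal test"
        )
    if state.outcome == 1:
        v = ppv(state.performance, prevalence)
        return v * utilities.u_tp + (1.0 - v) * utilities.u_fp
    if state.outcome == 0:
        v = npv(state.performance, prevalence)
        return v * utilities.u_tn + (1.0 - v) * utilities.u_fn
    raise ModelingError(
        f"outcome state at exit {state.exit_node_id!r} has no dichotomous outcome"
    )


def qaly(state: OutcomeState, config: CeaConfig) -> float:
    """QALYs accrued over the horizon by a patient ending in ``state``.

    The turnaround period is lived at the undiagnosed-state utility, the
    remainder of the horizon at the outcome state's expected utility. A TAT
    beyond the horizon is an error, not clamped: it signals a mis-specified
    tree or an unrealistically short horizon.
    """
    x = config.horizon_years
    tat = state.tat_years
    if tat > x:
        raise HorizonError(
            f"turnaround time {tat:.4f} y at exit {state.exit_node_id!r} exceeds "
            f"the {x} y horizon"
        )
    eu = expected_utility(state, config.prevalence, config.utilities)
    return tat * config.utilities.u_undiagnosed + (x - tat) * eu


def expected_qaly(states: Sequence[OutcomeState], config: CeaConfig) -> float:
    """Probability-weighted average QALY across all outcome states."""
    if not states:
        raise ModelingError("no outcome states")
    total_p = sum(s.path_probability for s in states)
    if abs(total_p - 1.0) > 1e-9:
        raise ModelingError(
            f"outcome-state probabilities sum to {total_p!r}, not 1"
        )
    return sum(s.path_probability * qaly(s, config) for s in states)


def cost_per_qaly(cost: float, qaly_value: float) -> float:
    """Cost-effectiveness ratio; requires a positive QALY denominator."""
    if qaly_value <= 0.0:
        raise ModelingError(
            f"expected QALY is {qaly_value!r} <= 0; cost per QALY undefined "
            "(strongly negative false-negative utilities can cause this)"
        )
    return cost / qaly_value


@dataclass(frozen=True)
class CeaResult:
    """Joint result of one deterministic cost-effectiveness evaluation."""

    expected_cost: float
    expected_qaly: float
    cost_per_qaly: float
    states: tuple[OutcomeState, ...]
    cost_map: Mapping[str, float]


def evaluate(
    tree: DiagnosticTree,
    perf_registry: Mapping[str, PerformanceLike],
    config: CeaConfig,
    *,
    overrides: Mapping[str, float] | None = None,
    validate: bool = True,
) -> CeaResult:
    """Expected cost, expected QALY and their ratio for one tree."""
    if validate:
        violations = validate_tree(tree)
        if violations:
            raise InvalidTreeError(violations)
    cost_map = expected_cost(tree, validate=False)
    states = outcome_states(
        tree, perf_registry, overrides=overrides, validate=False
    )
    eq = expected_qaly(states, config)
    root_cost = cost_map[tree.root_id]
    return CeaResult(
        expected_cost=root_cost,
        expected_qaly=eq,
        cost_per_qaly=cost_per_qaly(root_cost, eq),
        states=tuple(states),
        cost_map=cost_map,
    )


def adjust_for_inflation(
    original_cost: float, index_current: float, index_base: float
) -> float:
    """Rescale a historical cost by a price-index ratio.

    ``adjusted = original * index_current / index_base`` — e.g. the Medical
    Care CPI of the analysis month over that of the month the cost was
    published. Index values are supplied by the caller; nothing is fetched.
    """
    if index_base <= 0:
        raise ValueError(f"index_base must be positive, got {index_base}")
    if index_current <= 0:
        raise ValueError(f"index_current must be positive, got {index_current}")
    return original_cost * index_current / index_base
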