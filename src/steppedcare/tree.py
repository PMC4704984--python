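"""Cohort decision-tree model: build strategy trees, enumerate root-to-leaf
paths, and compute expected costs (AUD) and QALYs over the 28-week horizon.

The tree for each strategy arm is described declaratively (packaged
``data/topology.yaml`` by default, or a ``topology`` block in a user config).
Branch probabilities and resource counts are expressions over parameter names,
so the entire structure can be audited and amended without touching code.
Evaluation is by exhaustive path enumeration (the horizon is unrolled, so the
tree is finite and acyclic); expectations are probability-weighted sums over
paths.  Expressions evaluate elementwise over numpy arrays, which lets the PSA
push thousands of parameter draws through the tree in one vectorised pass.

QALY accounting: time in the depressive-episode state is weighted by the
severity-mixed episode utility (0.688 x moderate + 0.312 x mild by default);
time in remission/maintenance by the maintenance utility; weeks are converted
to years with the configured weeks-per-year.
"""

from __future__ import annotations

import ast
import math
import operator
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

from .parameters import ConfigError, ModelConfig, ParameterSet

__all__ = [
    "EPISODE",
    "MAINTENANCE",
    "RESOURCE_UNIT_COSTS",
    "StateSchedule",
    "TerminalNode",
    "Branch",
    "ChanceNode",
    "StrategyTree",
    "PathOutcome",
    "CohortResult",
    "IncrementalResult",
    "compile_expression",
    "build_strategy_tree",
    "enumerate_paths",
    "path_qaly",
    "path_cost",
    "expected_outcomes",
    "expected_outcomes_arrays",
    "episode_utility",
    "nmb",
    "icer",
    "average_cer",
    "incremental_summary",
]

EPISODE = "episode"
MAINTENANCE = "maintenance"
STATES = (EPISODE, MAINTENANCE)

#: resource key in a topology terminal -> unit-cost parameter name
RESOURCE_UNIT_COSTS: dict[str, str] = {
    "gp_plan": "cost_gp_plan",
    "gp_consultation": "cost_gp_consultation",
    "psychiatrist": "cost_psychiatrist",
    "psychologist_session": "cost_psychologist_session",
    "cbt_course": "cost_cbt_course",
    "mycompass": "cost_mycompass",
    "medication_cycle": "cost_medication_per_cycle",
}

_PROB_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# expression language: numbers, parameter names, + - * /, parentheses
# ---------------------------------------------------------------------------

_BINOPS = {ast.Add: operator.add, ast.Sub: operator.sub, ast.Mult: operator.mul, ast.Div: operator.truediv}
_UNARYOPS = {ast.USub: operator.neg, ast.UAdd: operator.pos}


@dataclass(frozen=True)
class Expression:
    """A compiled arithmetic expression over parameter names."""

    text: str
    names: frozenset[str]
    _func: Callable[[Mapping], object]

    def __call__(self, env: Mapping) -> object:
        try:
            return self._func(env)
        except KeyError as exc:
            raise ConfigError(
                f"expression {self.text!r}: unresolved parameter {exc.args[0]!r}"
            ) from exc


def compile_expression(text) -> Expression:
    """Compile a topology expression; rejects anything beyond arithmetic."""
    text = str(text)
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ConfigError(f"malformed expression {text!r}: {exc.msg}") from exc

    names: set[str] = set()

    def build(node) -> Callable[[Mapping], object]:
        if isinstance(node, ast.Expression):
            return build(node.body)
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            op, left, right = _BINOPS[type(node.op)], build(node.left), build(node.right)
            return lambda env: op(left(env), right(env))
        if isinstance(node, ast.UnaryOp) and type(node.op) in _UNARYOPS:
            op, val = _UNARYOPS[type(node.op)], build(node.operand)
            return lambda env: op(val(env))
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            const = float(node.value)
            return lambda env: const
        if isinstance(node, ast.Name):
            names.add(node.id)
            key = node.id
            return lambda env: env[key]
        raise ConfigError(f"unsupported construct {type(node).__name__!r} in expression {text!r}")

    func = build(tree)
    return Expression(text=text, names=frozenset(names), _func=func)


# ---------------------------------------------------------------------------
# tree node types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSchedule:
    """Weeks spent in each health state over the horizon, one entry per cycle."""

    cycle_states: tuple[str, ...]
    cycle_length_weeks: int

    @property
    def total_weeks(self) -> int:
        return len(self.cycle_states) * self.cycle_length_weeks

    def weeks_in(self, state: str) -> int:
        return self.cycle_states.count(state) * self.cycle_length_weeks


@dataclass(frozen=True)
class TerminalNode:
    name: str
    schedule: StateSchedule
    resources: tuple[tuple[str, Expression], ...]  # (resource key, count expression)


@dataclass(frozen=True)
class Branch:
    label: str
    probability: Expression
    child: "ChanceNode | TerminalNode"


@dataclass(frozen=True)
class ChanceNode:
    name: str
    branches: tuple[Branch, ...]


@dataclass(frozen=True)
class StrategyTree:
    strategy: str
    root: ChanceNode | TerminalNode
    parameter_names: frozenset[str]


@dataclass(frozen=True)
class PathOutcome:
    """One root-to-terminal path: joint probability, state schedule and
    realised expected resource tally."""

    probability: float
    terminal_name: str
    schedule: StateSchedule
    tally: dict[str, float]


@dataclass(frozen=True)
class CohortResult:
    """Expected cost (AUD) and QALYs for one strategy under one parameter set."""

    strategy: str
    expected_cost: float
    expected_qaly: float


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison, deltas taken as comparator - reference.

    With that sign convention a NEGATIVE incremental NMB favours the reference
    strategy (incremental_nmb = NMB(comparator) - NMB(reference)); every report
    written by the CLI states this in its header.
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    icer_note: str
    incremental_nmb: float
    wtp: float


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _parse_node(d: Mapping, config: ModelConfig, seen: set[str]) -> ChanceNode | TerminalNode:
    kind = d.get("kind")
    if kind == "terminal":
        states = tuple(d["states"])
        if len(states) != config.n_cycles:
            raise ConfigError(
                f"terminal {d.get('name')!r}: {len(states)} cycle states, expected {config.n_cycles}"
            )
        for s in states:
            if s not in STATES:
                raise ConfigError(f"terminal {d.get('name')!r}: unknown state {s!r}")
        resources = []
        for key, expr_text in d.get("resources", {}).items():
            if key not in RESOURCE_UNIT_COSTS:
                raise ConfigError(f"terminal {d.get('name')!r}: unknown resource {key!r}")
            expr = compile_expression(expr_text)
            seen.update(expr.names)
            resources.append((key, expr))
        return TerminalNode(
            name=d.get("name", "terminal"),
            schedule=StateSchedule(states, config.cycle_length_weeks),
            resources=tuple(resources),
        )
    if kind == "chance":
        branches = []
        for b in d["branches"]:
            expr = compile_expression(b["p"])
            seen.update(expr.names)
            branches.append(Branch(b.get("label", ""), expr, _parse_node(b["child"], config, seen)))
        if not branches:
            raise ConfigError(f"chance node {d.get('name')!r} has no branches")
        return ChanceNode(name=d.get("name", "chance"), branches=tuple(branches))
    raise ConfigError(f"node kind must be 'chance' or 'terminal', got {kind!r}")


def build_strategy_tree(strategy: str, config: ModelConfig) -> StrategyTree:
    """Build (and validate) the unrolled decision tree for one strategy arm."""
    if strategy not in config.strategy_names:
        raise ValueError(f"unknown strategy {strategy!r}; configured: {config.strategy_names}")
    if strategy not in config.topology:
        raise ConfigError(f"no topology for strategy {strategy!r}")
    seen: set[str] = set()
    root = _parse_node(config.topology[strategy]["root"], config, seen)
    unknown = seen - set(config.parameters)
    if unknown:
        raise ConfigError(f"{strategy}: topology references undeclared parameters {sorted(unknown)}")
    return StrategyTree(strategy=strategy, root=root, parameter_names=frozenset(seen))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _walk(node, env: Mapping, prob, out: list, check: bool) -> None:
    if isinstance(node, TerminalNode):
        out.append((prob, node))
        return
    branch_ps = [b.probability(env) for b in node.branches]
    if check:
        total = sum(branch_ps)
        if abs(total - 1.0) > _PROB_SUM_TOL or any(p < -_PROB_SUM_TOL or p > 1 + _PROB_SUM_TOL for p in branch_ps):
            raise ConfigError(
                f"chance node {node.name!r}: branch probabilities {branch_ps} do not form a distribution"
            )
    for b, p in zip(node.branches, branch_ps):
        _walk(b.child, env, prob * p, out, check)


def enumerate_paths(tree: StrategyTree, params: Mapping) -> list[PathOutcome]:
    """All root-to-terminal paths with joint probabilities and resource tallies.

    Path probabilities multiply along branches and sum to 1 over the tree
    (each chance node is checked to be a proper distribution under ``params``).
    """
    raw: list = []
    _walk(tree.root, params, 1.0, raw, check=True)
    paths = [
        PathOutcome(
            probability=float(p),
            terminal_name=t.name,
            schedule=t.schedule,
            tally={key: float(expr(params)) for key, expr in t.resources},
        )
        for p, t in raw
    ]
    total = sum(p.probability for p in paths)
    if abs(total - 1.0) > _PROB_SUM_TOL:
        raise ConfigError(f"{tree.strategy}: path probabilities sum to {total}, expected 1")
    return paths


def episode_utility(params: Mapping, config: ModelConfig):
    """Severity-mixed utility of the depressive-episode state."""
    return (
        config.proportion_moderate * params["utility_moderate"]
        + config.proportion_mild * params["utility_mild"]
    )


def path_qaly(schedule: StateSchedule, params: Mapping, config: ModelConfig):
    """QALYs for one path: sum over states of utility x weeks / weeks-per-year."""
    u_episode = episode_utility(params, config)
    u_maint = params["utility_maintenance"]
    return (
        u_episode * schedule.weeks_in(EPISODE) + u_maint * schedule.weeks_in(MAINTENANCE)
    ) / config.weeks_per_year


def path_cost(tally: Mapping[str, float], params: Mapping):
    """AUD cost of one path: inner product of resource counts and unit costs."""
    total = 0.0
    for key, count in tally.items():
        try:
            cost_name = RESOURCE_UNIT_COSTS[key]
        except KeyError:
            raise ConfigError(f"unknown resource {key!r}") from None
        try:
            unit = params[cost_name]
        except KeyError:
            raise ConfigError(f"missing unit-cost parameter {cost_name!r}") from None
        total = total + count * unit
    return total


def expected_outcomes(tree: StrategyTree, params: ParameterSet | Mapping, config: ModelConfig) -> CohortResult:
    """Probability-weighted expected cost and QALYs over all paths."""
    cost = 0.0
    qaly = 0.0
    for path in enumerate_paths(tree, params):
        cost += path.probability * path_cost(path.tally, params)
        qaly += path.probability * path_qaly(path.schedule, params, config)
    return CohortResult(strategy=tree.strategy, expected_cost=float(cost), expected_qaly=float(qaly))


def expected_outcomes_arrays(
    tree: StrategyTree, env: Mapping[str, np.ndarray], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`expected_outcomes` over arrays of parameter draws.

    ``env`` maps parameter names to equal-length arrays (one entry per draw);
    returns (cost, qaly) arrays of the same length.  Used by the PSA and the
    value-of-information estimators.
    """
    raw: list = []
    _walk(tree.root, env, 1.0, raw, check=False)
    cost = 0.0
    qaly = 0.0
    total_p = 0.0
    for p, terminal in raw:
        c = 0.0
        for key, expr in terminal.resources:
            c = c + expr(env) * env[RESOURCE_UNIT_COSTS[key]]
        cost = cost + p * c
        qaly = qaly + p * path_qaly(terminal.schedule, env, config)
        total_p = total_p + p
    if np.max(np.abs(total_p - 1.0)) > 1e-6:
        raise ConfigError(f"{tree.strategy}: path probabilities do not sum to 1")
    n = max((np.size(v) for v in env.values()), default=1)
    return np.broadcast_to(cost, (n,)).astype(float), np.broadcast_to(qaly, (n,)).astype(float)


# ---------------------------------------------------------------------------
# summary measures
# ---------------------------------------------------------------------------


def nmb(E: float, C: float, wtp: float) -> float:
    """Net monetary benefit: E x wtp - C (AUD)."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be >= 0, got {wtp}")
    return E * wtp - C


def icer(delta_cost: float, delta_qaly: float) -> tuple[float | None, str]:
    """Incremental cost-effectiveness ratio with a dominance annotation.

    Returns (value, note); value is None when delta_qaly == 0 (undefined).
    Negative ICERs are reported as-is, annotated with which side dominates.
    """
    if delta_qaly == 0:
        note = "undefined (no QALY difference)" if delta_cost != 0 else "undefined (identical outcomes)"
        return None, note
    value = delta_cost / delta_qaly
    note = ""
    if delta_qaly > 0 and delta_cost <= 0:
        note = "comparator dominates (cheaper, more effective)"
    elif delta_qaly < 0 and delta_cost >= 0:
        note = "reference dominates (comparator costlier, less effective)"
    return value, note


def average_cer(C: float, E: float) -> float:
    """Average cost-effectiveness ratio C/E (AUD per QALY); requires E > 0."""
    if E <= 0:
        raise ValueError(f"average CER requires positive effectiveness, got E={E}")
    return C / E


def incremental_summary(reference: CohortResult, comparator: CohortResult, wtp: float) -> IncrementalResult:
    """Incremental comparison with deltas = comparator - reference.

    incremental_nmb = delta_qaly x wtp - delta_cost = NMB(comparator) -
    NMB(reference): negative values favour the reference strategy.
    """
    dc = comparator.expected_cost - reference.expected_cost
    de = comparator.expected_qaly - reference.expected_qaly
    value, note = icer(dc, de)
    return IncrementalResult(
        reference=reference.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=de,
        icer=value,
        icer_note=note,
        incremental_nmb=de * wtp - dc,
        wtp=wtp,
    )
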