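"""Patient-level microsimulation and synthetic-trial generation.

The microsimulation walks individual patients down the same strategy trees the
cohort model enumerates, sampling a branch at every chance node.  Its
empirical cost/QALY means converge to the cohort expectations (central limit
theorem), which makes it the package's independent brute-force oracle: the
two implementations share only the tree description, not the arithmetic.

Fractional expected resource counts (e.g. 2.48 GP visits per episode cycle)
are realised per patient as Poisson draws with the stated mean, so the
microsimulation mean matches the cohort expectation while individual
trajectories carry integer utilisation.

The synthetic-trial generator emulates the Bernoulli trial outcomes behind
the published Beta(events, non-events) parameterisations, closing the loop
probability -> trial -> refitted Beta for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ModelConfig, ParameterSpec, Distribution
from .tree import (
    RESOURCE_UNIT_COSTS,
    ChanceNode,
    StateSchedule,
    TerminalNode,
    build_strategy_tree,
    path_cost,
    path_qaly,
)

__all__ = [
    "PatientTrajectory",
    "CohortSimulation",
    "SyntheticTrial",
    "simulate_cohort",
    "generate_trial",
    "fit_beta",
]


@dataclass(frozen=True)
class PatientTrajectory:
    """One simulated patient: per-cycle states, realised utilisation, cost, QALY."""

    patient_id: int
    strategy: str
    terminal_name: str
    cycle_states: tuple[str, ...]
    tally: dict[str, float]
    cost: float
    qaly: float


@dataclass
class CohortSimulation:
    """Vectorised container for n simulated trajectories of one strategy."""

    strategy: str
    n: int
    seed: int
    terminal_names: tuple[str, ...]
    schedules: tuple[StateSchedule, ...]
    terminal_index: np.ndarray  # (n,) index into terminal_names/schedules
    tallies: dict[str, np.ndarray]  # resource -> (n,) realised counts
    costs: np.ndarray  # (n,)
    qalys: np.ndarray  # (n,)

    @property
    def mean_cost(self) -> float:
        return float(self.costs.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qalys.mean())

    def trajectory(self, i: int) -> PatientTrajectory:
        t = int(self.terminal_index[i])
        return PatientTrajectory(
            patient_id=i,
            strategy=self.strategy,
            terminal_name=self.terminal_names[t],
            cycle_states=self.schedules[t].cycle_states,
            tally={k: float(v[i]) for k, v in self.tallies.items()},
            cost=float(self.costs[i]),
            qaly=float(self.qalys[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table: patient_id, strategy, cycle, state,
        cost_aud, qaly (cost and QALY are per patient, repeated per cycle)."""
        n_cycles = len(self.schedules[0].cycle_states)
        states = np.array([s.cycle_states for s in self.schedules])  # (T, cycles)
        per_patient = states[self.terminal_index]  # (n, cycles)
        return pd.DataFrame(
            {
                "patient_id": np.repeat(np.arange(self.n), n_cycles),
                "strategy": self.strategy,
                "cycle": np.tile(np.arange(1, n_cycles + 1), self.n),
                "state": per_patient.ravel(),
                "cost_aud": np.repeat(self.costs, n_cycles),
                "qaly": np.repeat(self.qalys, n_cycles),
            }
        )


def simulate_cohort(
    config: ModelConfig, strategy: str, params: Mapping, n: int, seed: int
) -> tuple[float, float, CohortSimulation]:
    """Simulate n independent patient trajectories through one strategy tree.

    Returns (mean cost, mean QALY, simulation).  Branches are sampled at each
    chance node per patient; resource counts are Poisson draws around each
    terminal's expected tally.  Fully reproducible for a given seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tree = build_strategy_tree(strategy, config)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))

    terminals: list[TerminalNode] = []
    assign = np.empty(n, dtype=int)

    def walk(node, idx: np.ndarray) -> None:
        if isinstance(node, TerminalNode):
            terminals.append(node)
            assign[idx] = len(terminals) - 1
            return
        probs = [float(b.probability(params)) for b in node.branches]
        edges = np.cumsum(probs)
        choice = np.searchsorted(edges, rng.random(idx.size), side="right")
        choice = np.minimum(choice, len(probs) - 1)  # guard float round-off at 1.0
        for j, branch in enumerate(node.branches):
            sub = idx[choice == j]
            if sub.size:
                walk(branch.child, sub)

    walk(tree.root, np.arange(n))

    resources = sorted({key for t in terminals for key, _ in t.resources})
    tallies = {key: np.zeros(n) for key in resources}
    costs = np.zeros(n)
    qalys = np.empty(n)
    for t_idx, terminal in enumerate(terminals):
        members = np.flatnonzero(assign == t_idx)
        qalys[members] = path_qaly(terminal.schedule, params, config)
        for key, expr in terminal.resources:
            mean = float(expr(params))
            counts = rng.poisson(mean, members.size).astype(float)
            tallies[key][members] = counts
            costs[members] += counts * float(params[RESOURCE_UNIT_COSTS[key]])

    sim = CohortSimulation(
        strategy=strategy,
        n=n,
        seed=int(seed),
        terminal_names=tuple(t.name for t in terminals),
        schedules=tuple(t.schedule for t in terminals),
        terminal_index=assign,
        tallies=tallies,
        costs=costs,
        qalys=qalys,
    )
    return sim.mean_cost, sim.mean_qaly, sim


@dataclass(frozen=True)
class SyntheticTrial:
    """Aggregate outcome of an emulated Bernoulli trial."""

    parameter: str
    true_probability: float
    n: int
    successes: int

    @property
    def success_fraction(self) -> float:
        return self.successes / self.n


def generate_trial(p: float, n: int, seed: int, parameter: str = "") -> SyntheticTrial:
    """Draw the success count of an n-subject Bernoulli trial with rate p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    return SyntheticTrial(
        parameter=parameter,
        true_probability=float(p),
        n=int(n),
        successes=int(rng.binomial(n, p)),
    )


def fit_beta(successes: int, failures: int, name: str = "fitted") -> ParameterSpec:
    """Beta(events, non-events) specification from trial counts.

    Follows the published convention that a probability observed as s events
    out of s+f subjects is carried as Beta(s, f) with point estimate s/(s+f);
    both counts must be positive for the Beta to be proper.
    """
    if successes + failures < 1:
        raise ValueError("at least one subject is required")
    if successes <= 0 or failures <= 0:
        raise ValueError("both event and non-event counts must be positive to define a Beta")
    total = successes + failures
    return ParameterSpec(
        name=name,
        role="probability",
        point_estimate=successes / total,
        distribution=Distribution("beta", (float(successes), float(failures))),
        source_note=f"fitted from synthetic trial: {successes}/{total} events",
    )
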