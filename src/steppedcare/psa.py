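"""Probabilistic sensitivity analysis: propagate the parameter distributions
through the cohort model, summarise the joint cost/QALY distribution, and
compute CEAC curves and cost-effectiveness-plane exports.

Common random numbers: within an iteration the same parameter draw is applied
to all strategies (shared parameters such as utilities make per-strategy draws
incoherent), so between-strategy contrasts are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ModelConfig, ParameterSet, sample_parameter_arrays
from .tree import build_strategy_tree, expected_outcomes_arrays

__all__ = [
    "PSADraws",
    "StrategySummary",
    "PSASummary",
    "CEACCurve",
    "run_psa",
    "summarize_psa",
    "ceac",
    "export_ce_plane",
    "plot_ceac",
    "plot_ce_plane",
]


@dataclass
class PSADraws:
    """Per-iteration (cost, QALY) pairs for all strategies plus the sampled
    parameter values; regenerating with the same seed is bit-identical."""

    n: int
    seed: int
    strategy_names: tuple[str, ...]
    parameters: dict[str, np.ndarray]  # name -> (n,)
    costs: dict[str, np.ndarray]  # strategy -> (n,)
    qalys: dict[str, np.ndarray]  # strategy -> (n,)

    def nmb(self, wtp: float) -> dict[str, np.ndarray]:
        return {s: self.qalys[s] * wtp - self.costs[s] for s in self.strategy_names}

    def parameter_set(self, config: ModelConfig, i: int) -> ParameterSet:
        return ParameterSet.from_values(
            config, {name: float(v[i]) for name, v in self.parameters.items()}
        )

    def validate(self, config: ModelConfig) -> None:
        qaly_max = config.horizon_weeks / config.weeks_per_year
        for s in self.strategy_names:
            if np.any(self.costs[s] < 0):
                raise ValueError(f"{s}: negative per-iteration cost")
            if np.any(self.qalys[s] < 0) or np.any(self.qalys[s] > qaly_max + 1e-12):
                raise ValueError(f"{s}: per-iteration QALY outside [0, {qaly_max}]")


@dataclass(frozen=True)
class StrategySummary:
    strategy: str
    mean_cost: float
    cost_ci: tuple[float, float]
    mean_qaly: float
    qaly_ci: tuple[float, float]
    mean_nmb: float
    nmb_ci: tuple[float, float]
    average_cer: float


@dataclass(frozen=True)
class PSASummary:
    wtp: float
    n: int
    strategies: tuple[StrategySummary, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": s.strategy,
                "mean_cost_aud": s.mean_cost,
                "cost_ci_lo": s.cost_ci[0],
                "cost_ci_hi": s.cost_ci[1],
                "mean_qaly": s.mean_qaly,
                "qaly_ci_lo": s.qaly_ci[0],
                "qaly_ci_hi": s.qaly_ci[1],
                "mean_nmb": s.mean_nmb,
                "nmb_ci_lo": s.nmb_ci[0],
                "nmb_ci_hi": s.nmb_ci[1],
                "average_cer": s.average_cer,
            }
            for s in self.strategies
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CEACCurve:
    """Probability that each strategy has the highest NMB, per WTP value."""

    wtp: np.ndarray  # (m,)
    strategy_names: tuple[str, ...]
    probabilities: np.ndarray  # (m, n_strategies), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=[f"p_{s.lower()}" for s in self.strategy_names])
        df.insert(0, "wtp", self.wtp)
        return df

    def probability(self, strategy: str, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probabilities[i, self.strategy_names.index(strategy)])


def run_psa(config: ModelConfig, n: int | None = None, seed: int | None = None) -> PSADraws:
    """Run the PSA: n joint parameter draws pushed through every strategy tree.

    Defaults to ``config.psa_iterations`` iterations and ``config.rng_seed``.
    """
    n = config.psa_iterations if n is None else int(n)
    seed = config.rng_seed if seed is None else int(seed)
    if n < 1:
        raise ValueError(f"psa iterations must be >= 1, got {n}")
    env = sample_parameter_arrays(config, n, seed)
    costs: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    for strategy in config.strategy_names:
        tree = build_strategy_tree(strategy, config)
        costs[strategy], qalys[strategy] = expected_outcomes_arrays(tree, env, config)
    draws = PSADraws(
        n=n,
        seed=seed,
        strategy_names=tuple(config.strategy_names),
        parameters=env,
        costs=costs,
        qalys=qalys,
    )
    draws.validate(config)
    return draws


def _ci(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def summarize_psa(draws: PSADraws, wtp: float) -> PSASummary:
    """Means, equal-tailed 95% credible intervals, average CER and mean NMB."""
    if draws.n < 2:
        raise ValueError("summarising a PSA requires at least 2 iterations")
    rows = []
    for s in draws.strategy_names:
        cost, qaly = draws.costs[s], draws.qalys[s]
        nmb = qaly * wtp - cost
        rows.append(
            StrategySummary(
                strategy=s,
                mean_cost=float(cost.mean()),
                cost_ci=_ci(cost),
                mean_qaly=float(qaly.mean()),
                qaly_ci=_ci(qaly),
                mean_nmb=float(nmb.mean()),
                nmb_ci=_ci(nmb),
                average_cer=float(cost.mean() / qaly.mean()),
            )
        )
    return PSASummary(wtp=float(wtp), n=draws.n, strategies=tuple(rows))


def _winners(draws: PSADraws, wtp: float) -> np.ndarray:
    """Index of the highest-NMB strategy per iteration; ties broken by lowest
    cost, then by declaration order (deterministic for degenerate configs)."""
    nmb = np.column_stack([draws.qalys[s] * wtp - draws.costs[s] for s in draws.strategy_names])
    cost = np.column_stack([draws.costs[s] for s in draws.strategy_names])
    best = np.zeros(draws.n, dtype=int)
    for j in range(1, nmb.shape[1]):
        better = nmb[:, j] > nmb[np.arange(draws.n), best]
        tie = nmb[:, j] == nmb[np.arange(draws.n), best]
        cheaper = cost[:, j] < cost[np.arange(draws.n), best]
        best = np.where(better | (tie & cheaper), j, best)
    return best


def ceac(draws: PSADraws, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve over a WTP grid: the fraction of
    iterations in which each strategy attains the highest NMB."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be nonempty")
    S = len(draws.strategy_names)
    probs = np.empty((grid.size, S))
    for i, wtp in enumerate(grid):
        winners = _winners(draws, float(wtp))
        probs[i] = np.bincount(winners, minlength=S) / draws.n
    return CEACCurve(wtp=grid, strategy_names=draws.strategy_names, probabilities=probs)


def ce_plane_frame(draws: PSADraws, reference: str) -> pd.DataFrame:
    """Per-iteration incremental (QALY, cost) pairs of each comparator versus
    ``reference`` (comparator minus reference)."""
    if reference not in draws.strategy_names:
        raise ValueError(f"unknown reference strategy {reference!r}")
    frames = []
    for s in draws.strategy_names:
        if s == reference:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "iteration": np.arange(draws.n),
                    "comparator": s,
                    "delta_qaly": draws.qalys[s] - draws.qalys[reference],
                    "delta_cost_aud": draws.costs[s] - draws.costs[reference],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def export_ce_plane(draws: PSADraws, reference: str, path) -> pd.DataFrame:
    """Write the cost-effectiveness plane as CSV; returns the frame written."""
    df = ce_plane_frame(draws, reference)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def plot_ceac(curve: CEACCurve, path, landmarks: Sequence[float] = (50_000.0,)) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for j, s in enumerate(curve.strategy_names):
        ax.plot(curve.wtp, curve.probabilities[:, j], label=s)
    for lm in landmarks:
        ax.axvline(lm, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("Willingness to pay (AUD per QALY)")
    ax.set_ylabel("Probability of highest NMB")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(draws: PSADraws, reference: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ce_plane_frame(draws, reference)
    fig, ax = plt.subplots(figsize=(6, 6))
    for s, sub in df.groupby("comparator"):
        ax.scatter(sub["delta_qaly"], sub["delta_cost_aud"], s=4, alpha=0.3, label=f"{s} vs {reference}")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (AUD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
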