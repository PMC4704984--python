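"""One-way (univariate) and threshold sensitivity analysis.

Deterministic sweeps: one parameter varies over a range while every other
parameter sits at its point estimate; at each grid point the model reports the
expected NMB of the NMB-optimal strategy.  The threshold search locates the
parameter value at which the identity of the optimal strategy changes, by
coarse scan followed by bisection.

The shipped default sweep brackets for the three headline parameters follow
the published uncertainty-analysis table: myCompass non-adherence 0-0.35,
CBT delivery cost 0-619 AUD, myCompass delivery cost 0-564 AUD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelConfig, point_parameter_set
from .tree import build_strategy_tree, expected_outcomes

__all__ = [
    "DEFAULT_SWEEPS",
    "OneWayResult",
    "ThresholdResult",
    "one_way",
    "threshold_search",
]

DEFAULT_SWEEPS: dict[str, tuple[float, float]] = {
    "nonadherence_acute_mycompass": (0.0, 0.35),
    "cost_cbt_course": (0.0, 619.0),
    "cost_mycompass": (0.0, 564.0),
}


@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    lo: float
    hi: float
    wtp: float
    grid: np.ndarray  # evaluated parameter values
    optimal_strategy: tuple[str, ...]  # optimal strategy at each grid point
    optimal_nmb: np.ndarray  # expected NMB of the optimal strategy
    nmb_by_strategy: dict[str, np.ndarray]

    @property
    def lowest(self) -> float:
        return float(self.optimal_nmb.min())

    @property
    def highest(self) -> float:
        return float(self.optimal_nmb.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "value": self.grid,
                "optimal_strategy": list(self.optimal_strategy),
                "expected_nmb": self.optimal_nmb,
            }
        )


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    wtp: float
    lo: float
    hi: float
    threshold: float | None  # None when the optimal strategy never changes
    strategy_below: str | None
    strategy_above: str | None


def _nmb_at(config: ModelConfig, trees, base: dict, param: str, value: float, wtp: float) -> dict[str, float]:
    env = dict(base)
    env[param] = float(value)
    out = {}
    for strategy, tree in trees.items():
        r = expected_outcomes(tree, env, config)
        out[strategy] = r.expected_qaly * wtp - r.expected_cost
    return out


def _optimal(nmbs: dict[str, float], order: tuple[str, ...]) -> str:
    best = order[0]
    for s in order[1:]:
        if nmbs[s] > nmbs[best]:
            best = s
    return best


def one_way(
    config: ModelConfig,
    param: str,
    lo: float | None = None,
    hi: float | None = None,
    wtp: float | None = None,
    grid_points: int = 101,
) -> OneWayResult:
    """Sweep one parameter over [lo, hi] with all others at point estimates.

    ``lo``/``hi`` default to the shipped bracket for the headline parameters
    (:data:`DEFAULT_SWEEPS`), otherwise to the parameter's declared bounds.
    """
    if param not in config.parameters:
        raise ValueError(f"unknown parameter {param!r}")
    if lo is None or hi is None:
        if param in DEFAULT_SWEEPS:
            d_lo, d_hi = DEFAULT_SWEEPS[param]
        else:
            b_lo, b_hi = config.parameters[param].effective_bounds()
            d_lo = b_lo
            d_hi = b_hi if np.isfinite(b_hi) else 2.0 * config.parameters[param].point_estimate
        lo = d_lo if lo is None else lo
        hi = d_hi if hi is None else hi
    if lo > hi:
        raise ValueError(f"invalid range: lo={lo} > hi={hi}")
    wtp = config.wtp_default if wtp is None else float(wtp)
    if grid_points < 1:
        raise ValueError("grid_points must be >= 1")

    trees = {s: build_strategy_tree(s, config) for s in config.strategy_names}
    base = dict(point_parameter_set(config))
    grid = np.linspace(lo, hi, grid_points) if grid_points > 1 else np.array([float(lo)])
    order = tuple(config.strategy_names)
    nmb_by_strategy = {s: np.empty(grid.size) for s in order}
    optimal: list[str] = []
    for i, v in enumerate(grid):
        nmbs = _nmb_at(config, trees, base, param, v, wtp)
        for s in order:
            nmb_by_strategy[s][i] = nmbs[s]
        optimal.append(_optimal(nmbs, order))
    optimal_nmb = np.array([nmb_by_strategy[s][i] for i, s in enumerate(optimal)])
    return OneWayResult(
        parameter=param,
        lo=float(lo),
        hi=float(hi),
        wtp=wtp,
        grid=grid,
        optimal_strategy=tuple(optimal),
        optimal_nmb=optimal_nmb,
        nmb_by_strategy=nmb_by_strategy,
    )


def threshold_search(
    config: ModelConfig,
    param: str,
    lo: float,
    hi: float,
    wtp: float | None = None,
    tol: float = 0.01,
    scan_points: int = 101,
) -> ThresholdResult:
    """Locate the parameter value where the NMB-optimal strategy changes.

    A coarse scan brackets the first change of optimum over [lo, hi]; bisection
    on the NMB difference between the two competing strategies then refines the
    crossing to absolute tolerance ``tol`` (parameter units).  Returns a
    ``threshold`` of None when the optimum is constant across the scan.
    """
    if not lo < hi:
        raise ValueError(f"invalid bracket: lo={lo} must be < hi={hi}")
    if param not in config.parameters:
        raise ValueError(f"unknown parameter {param!r}")
    wtp = config.wtp_default if wtp is None else float(wtp)
    trees = {s: build_strategy_tree(s, config) for s in config.strategy_names}
    base = dict(point_parameter_set(config))
    order = tuple(config.strategy_names)

    grid = np.linspace(lo, hi, scan_points)
    opt = [_optimal(_nmb_at(config, trees, base, param, v, wtp), order) for v in grid]
    change = next((i for i in range(1, len(opt)) if opt[i] != opt[i - 1]), None)
    if change is None:
        return ThresholdResult(param, wtp, float(lo), float(hi), None, None, None)

    s_left, s_right = opt[change - 1], opt[change]
    a, b = float(grid[change - 1]), float(grid[change])

    def gap(v: float) -> float:
        nmbs = _nmb_at(config, trees, base, param, v, wtp)
        return nmbs[s_left] - nmbs[s_right]

    fa = gap(a)
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = gap(m)
        if (fa >= 0) == (fm >= 0):
            a, fa = m, fm
        else:
            b = m
    threshold = 0.5 * (a + b)
    return ThresholdResult(
        parameter=param,
        wtp=wtp,
        lo=float(lo),
        hi=float(hi),
        threshold=float(threshold),
        strategy_below=s_left,
        strategy_above=s_right,
    )
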