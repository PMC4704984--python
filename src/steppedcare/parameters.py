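"""Model inputs: parameter specifications, validation, and PSA sampling.

Every quantity the decision model consumes — transition probabilities,
health-state utilities, resource counts, unit costs (AUD, 2013/14) and
population-scaling constants — is a named :class:`ParameterSpec` carrying a
deterministic point estimate and an uncertainty distribution for probabilistic
sensitivity analysis.  The packaged default configuration holds the full
published input table for the three-arm stepped-care depression model
(myCompass internet CBT, face-to-face CBT, antidepressant treatment as usual).

Conventions
-----------
* Beta distributions are parameterised as (events, non-events); their analytic
  mean is alpha/(alpha+beta).
* Lognormal distributions are parameterised on the log scale (mu, sigma).
* Base-case (deterministic) evaluations use the published point estimates as
  printed; PSA draws come from the published distributions.  For a few rows
  the two are not perfectly consistent at the third decimal; both are stored
  verbatim and neither is recomputed from the other.
* Sampling uses one root seed with a per-parameter substream derived from a
  stable hash of the parameter name, so adding or removing one parameter does
  not reshuffle the draws of the others.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "Distribution",
    "ParameterSpec",
    "ModelConfig",
    "ParameterSet",
    "distribution_mean",
    "default_config",
    "load_config",
    "save_config",
    "point_parameter_set",
    "sample_parameter_arrays",
    "sample_parameters",
]

ROLES = ("probability", "utility", "unit-cost", "resource-count", "scaling-constant")
DIST_KINDS = ("beta", "lognormal", "fixed", "uniform")

#: default willingness-to-pay grid for CEACs: 0..100,000 AUD/QALY in 1,000 steps,
#: covering both decision landmarks (50,000 and 65,000) with margin.
DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 100_001, 1_000))


class ConfigError(ValueError):
    """A configuration file or parameter block violates the documented schema."""


@dataclass(frozen=True)
class Distribution:
    """Uncertainty distribution of one model input.

    kind is one of ``beta`` (alpha, beta), ``lognormal`` (mu, sigma on the log
    scale), ``uniform`` (lo, hi) or ``fixed`` (no arguments; the parameter is
    degenerate at its point estimate).
    """

    kind: str
    args: tuple[float, ...] = ()

    def validate(self, name: str) -> None:
        if self.kind not in DIST_KINDS:
            raise ConfigError(f"{name}: unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if len(self.args) != 2 or self.args[0] <= 0 or self.args[1] <= 0:
                raise ConfigError(f"{name}: beta requires alpha > 0 and beta > 0, got {self.args}")
        elif self.kind == "lognormal":
            if len(self.args) != 2 or self.args[1] < 0:
                raise ConfigError(f"{name}: lognormal requires (mu, sigma >= 0), got {self.args}")
        elif self.kind == "uniform":
            if len(self.args) != 2 or self.args[0] > self.args[1]:
                raise ConfigError(f"{name}: uniform requires lo <= hi, got {self.args}")
        elif self.kind == "fixed" and self.args:
            raise ConfigError(f"{name}: fixed distribution takes no arguments, got {self.args}")


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with point estimate, distribution and bounds."""

    name: str
    role: str
    point_estimate: float
    distribution: Distribution = Distribution("fixed")
    bounds: tuple[float, float] | None = None
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"{self.name}: unknown role {self.role!r}")
        self.distribution.validate(self.name)
        lo, hi = self.effective_bounds()
        if not lo <= self.point_estimate <= hi:
            raise ConfigError(
                f"{self.name}: point estimate {self.point_estimate} outside bounds [{lo}, {hi}]"
            )
        if self.role in ("probability", "utility") and not (lo >= 0.0 and hi <= 1.0):
            raise ConfigError(f"{self.name}: {self.role} bounds must lie within [0, 1]")
        if self.role in ("unit-cost", "resource-count") and self.point_estimate < 0:
            raise ConfigError(f"{self.name}: {self.role} point estimate must be >= 0")

    def effective_bounds(self) -> tuple[float, float]:
        """Declared bounds, defaulting to [0, 1] for probabilities/utilities and
        [0, inf) for costs and counts."""
        if self.bounds is not None:
            return (float(self.bounds[0]), float(self.bounds[1]))
        if self.role in ("probability", "utility"):
            return (0.0, 1.0)
        return (0.0, float("inf"))


def distribution_mean(spec: ParameterSpec) -> float:
    """Analytic mean of the parameter's uncertainty distribution.

    beta -> alpha/(alpha+beta); lognormal(mu, sigma) -> exp(mu + sigma^2/2);
    uniform -> midpoint; fixed -> the point estimate.
    """
    d = spec.distribution
    if d.kind == "beta":
        a, b = d.args
        return a / (a + b)
    if d.kind == "lognormal":
        mu, sigma = d.args
        return float(np.exp(mu + sigma**2 / 2.0))
    if d.kind == "uniform":
        lo, hi = d.args
        return (lo + hi) / 2.0
    return float(spec.point_estimate)


class ParameterSet(dict):
    """A realised value for every declared parameter (one deterministic
    evaluation or one PSA draw)."""

    @classmethod
    def from_values(cls, config: "ModelConfig", values: Mapping[str, float]) -> "ParameterSet":
        ps = cls(values)
        ps.validate(config)
        return ps

    def validate(self, config: "ModelConfig") -> None:
        declared = set(config.parameters)
        got = set(self)
        if declared != got:
            missing = declared - got
            extra = got - declared
            raise ConfigError(f"parameter set mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, value in self.items():
            lo, hi = config.parameters[name].effective_bounds()
            if not lo <= value <= hi:
                raise ConfigError(f"{name}: value {value} outside bounds [{lo}, {hi}]")


@dataclass
class ModelConfig:
    """Complete, validated model configuration.

    The default instance reproduces the published input tables verbatim; see
    :func:`default_config`.  ``topology`` holds the decision-tree description
    for each strategy (see :mod:`steppedcare.tree` for the node schema).
    """

    strategy_names: tuple[str, ...] = ("TAU", "CBT", "myCompass")
    cycle_length_weeks: int = 7
    n_cycles: int = 4
    weeks_per_year: int = 52
    wtp_default: float = 50_000.0
    proportion_moderate: float = 0.688
    proportion_mild: float = 0.312
    psa_iterations: int = 10_000
    rng_seed: int = 2013
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    parameters: dict[str, ParameterSpec] = field(default_factory=dict)
    topology: dict = field(default_factory=dict)

    @property
    def horizon_weeks(self) -> int:
        return self.cycle_length_weeks * self.n_cycles

    def validate(self) -> None:
        if abs(self.proportion_moderate + self.proportion_mild - 1.0) > 1e-9:
            raise ConfigError(
                "severity proportions must sum to 1, got "
                f"{self.proportion_moderate} + {self.proportion_mild}"
            )
        if len(self.strategy_names) < 2:
            raise ConfigError("at least two strategies are required")
        if self.cycle_length_weeks <= 0 or self.n_cycles <= 0:
            raise ConfigError("cycle_length_weeks and n_cycles must be positive")
        grid = np.asarray(self.wtp_grid, dtype=float)
        if grid.size == 0 or grid[0] < 0 or np.any(np.diff(grid) <= 0):
            raise ConfigError("wtp_grid must be nonnegative and strictly increasing")
        if self.psa_iterations < 1:
            raise ConfigError("psa_iterations must be >= 1")
        for name, spec in self.parameters.items():
            if name != spec.name:
                raise ConfigError(f"parameter key {name!r} does not match spec name {spec.name!r}")
        for strategy in self.strategy_names:
            if strategy not in self.topology:
                raise ConfigError(f"no tree topology declared for strategy {strategy!r}")


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: ParameterSpec) -> dict:
    d: dict = {
        "role": spec.role,
        "point_estimate": float(spec.point_estimate),
        "distribution": {"kind": spec.distribution.kind},
    }
    if spec.distribution.args:
        d["distribution"]["args"] = [float(a) for a in spec.distribution.args]
    if spec.bounds is not None:
        d["bounds"] = [float(spec.bounds[0]), float(spec.bounds[1])]
    if spec.source_note:
        d["source_note"] = spec.source_note
    return d


def _spec_from_dict(name: str, d: Mapping) -> ParameterSpec:
    try:
        dist_d = d.get("distribution", {"kind": "fixed"})
        dist = Distribution(dist_d["kind"], tuple(float(a) for a in dist_d.get("args", ())))
        bounds = d.get("bounds")
        return ParameterSpec(
            name=name,
            role=d["role"],
            point_estimate=float(d["point_estimate"]),
            distribution=dist,
            bounds=tuple(float(b) for b in bounds) if bounds is not None else None,
            source_note=d.get("source_note", ""),
        )
    except KeyError as exc:
        raise ConfigError(f"parameter {name!r}: missing field {exc.args[0]!r}") from exc


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "strategy_names": list(config.strategy_names),
        "cycle_length_weeks": config.cycle_length_weeks,
        "n_cycles": config.n_cycles,
        "weeks_per_year": config.weeks_per_year,
        "wtp_default": config.wtp_default,
        "severity_mix": {
            "moderate": config.proportion_moderate,
            "mild": config.proportion_mild,
        },
        "psa_iterations": config.psa_iterations,
        "rng_seed": config.rng_seed,
        "wtp_grid": [float(x) for x in config.wtp_grid],
        "parameters": {name: _spec_to_dict(s) for name, s in config.parameters.items()},
        "topology": config.topology,
    }


def config_from_dict(d: Mapping) -> ModelConfig:
    try:
        severity = d.get("severity_mix", {})
        config = ModelConfig(
            strategy_names=tuple(d["strategy_names"]),
            cycle_length_weeks=int(d["cycle_length_weeks"]),
            n_cycles=int(d["n_cycles"]),
            weeks_per_year=int(d.get("weeks_per_year", 52)),
            wtp_default=float(d["wtp_default"]),
            proportion_moderate=float(severity["moderate"]),
            proportion_mild=float(severity["mild"]),
            psa_iterations=int(d.get("psa_iterations", 10_000)),
            rng_seed=int(d.get("rng_seed", 2013)),
            wtp_grid=tuple(float(x) for x in d.get("wtp_grid", DEFAULT_WTP_GRID)),
            parameters={name: _spec_from_dict(name, pd) for name, pd in d["parameters"].items()},
            topology=dict(d["topology"]) if "topology" in d else _packaged_topology(),
        )
    except KeyError as exc:
        raise ConfigError(f"missing configuration field {exc.args[0]!r}") from exc
    config.validate()
    return config


def _packaged_yaml(filename: str) -> dict:
    text = resources.files("steppedcare.data").joinpath(filename).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def _packaged_topology() -> dict:
    return _packaged_yaml("topology.yaml")


def default_config() -> ModelConfig:
    """The packaged default configuration: the published parameter tables plus
    the documented tree-topology reconstruction."""
    return config_from_dict(_packaged_yaml("default_config.yaml"))


def load_config(path) -> ModelConfig:
    """Load and validate a configuration from a YAML file.

    A file without a ``topology`` block uses the packaged default topology.
    """
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise ConfigError(f"{path}: not a mapping")
    return config_from_dict(d)


def save_config(config: ModelConfig, path) -> None:
    """Write a configuration (including its topology) to YAML; the round trip
    through :func:`load_config` is lossless."""
    config.validate()
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# deterministic values and PSA sampling
# ---------------------------------------------------------------------------

def point_parameter_set(config: ModelConfig) -> ParameterSet:
    """Published point estimates for every parameter (base-case values)."""
    return ParameterSet.from_values(
        config, {name: float(s.point_estimate) for name, s in config.parameters.items()}
    )


def _substream(root_seed: int, name: str) -> np.random.Generator:
    # stable per-parameter stream: independent of declaration order and of the
    # presence of other parameters
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())]))


def _draw(spec: ParameterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    d = spec.distribution
    if d.kind == "fixed":
        return np.full(n, float(spec.point_estimate))
    if d.kind == "beta":
        out = rng.beta(d.args[0], d.args[1], size=n)
    elif d.kind == "lognormal":
        out = rng.lognormal(d.args[0], d.args[1], size=n)
    else:  # uniform
        out = rng.uniform(d.args[0], d.args[1], size=n)
    lo, hi = spec.effective_bounds()
    # out-of-bounds draws (e.g. a lognormal for a probability-role parameter)
    # are resampled, which truncates without distorting in-bounds quantiles
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        if d.kind == "beta":
            out[bad] = rng.beta(d.args[0], d.args[1], size=int(bad.sum()))
        elif d.kind == "lognormal":
            out[bad] = rng.lognormal(d.args[0], d.args[1], size=int(bad.sum()))
        else:
            out[bad] = rng.uniform(d.args[0], d.args[1], size=int(bad.sum()))
    else:
        out = np.clip(out, lo, hi)
    return out


def sample_parameter_arrays(config: ModelConfig, n: int, seed: int) -> dict[str, np.ndarray]:
    """n joint PSA draws as a mapping name -> array of shape (n,).

    Each parameter is drawn independently from its own distribution on its own
    seeded substream; fixed parameters are constant at their point estimate.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return {name: _draw(spec, n, _substream(seed, name)) for name, spec in config.parameters.items()}


def sample_parameters(config: ModelConfig, n: int, seed: int) -> list[ParameterSet]:
    """n joint PSA draws as a list of validated :class:`ParameterSet`."""
    arrays = sample_parameter_arrays(config, n, seed)
    names = list(arrays)
    return [
        ParameterSet.from_values(config, {name: float(arrays[name][i]) for name in names})
        for i in range(n)
    ]
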