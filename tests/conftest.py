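"""Shared fixtures: the packaged default model and small synthetic configs."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

from steppedcare import ModelConfig, default_config, point_parameter_set
from steppedcare.parameters import Distribution, ParameterSpec

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return default_config()


@pytest.fixture(scope="session")
def point_params(config):
    return point_parameter_set(config)


def make_deterministic(config: ModelConfig) -> ModelConfig:
    """Copy of a config with every distribution degenerate at its point estimate."""
    params = {
        name: dataclasses.replace(spec, distribution=Distribution("fixed"))
        for name, spec in config.parameters.items()
    }
    return dataclasses.replace(config, parameters=params)


def two_arm_toy_config(
    p_dist: Distribution = Distribution("beta", (2.0, 3.0)),
    p_point: float = 0.4,
    certain_cost: float = 600.0,
    certain_cost_b: float | None = None,
) -> ModelConfig:
    """Tiny two-strategy model with analytically tractable NMB.

    One cycle of 7 weeks; utilities fixed at episode=0, maintenance=1, so one
    cycle in maintenance is worth 7/52 QALYs.  Strategy "Gamble" reaches
    maintenance with probability ``p`` at zero cost; strategy "Certain" always
    reaches maintenance at a fixed cost.  At willingness-to-pay 52000/7 the
    NMBs are 1000*p and 1000 - cost, so every value-of-information quantity
    has a closed form in the Beta distribution of p.
    """
    parameters = {
        "p_success": ParameterSpec("p_success", "probability", p_point, p_dist),
        "utility_mild": ParameterSpec("utility_mild", "utility", 0.0),
        "utility_moderate": ParameterSpec("utility_moderate", "utility", 0.0),
        "utility_maintenance": ParameterSpec("utility_maintenance", "utility", 1.0),
        "cost_gp_plan": ParameterSpec("cost_gp_plan", "unit-cost", certain_cost),
        "cost_gp_consultation": ParameterSpec(
            "cost_gp_consultation", "unit-cost",
            certain_cost if certain_cost_b is None else certain_cost_b,
        ),
    }
    topology = {
        "Gamble": {
            "root": {
                "kind": "chance",
                "name": "outcome",
                "branches": [
                    {
                        "label": "success",
                        "p": "p_success",
                        "child": {
                            "kind": "terminal",
                            "name": "well",
                            "states": ["maintenance"],
                            "resources": {},
                        },
                    },
                    {
                        "label": "failure",
                        "p": "1 - p_success",
                        "child": {
                            "kind": "terminal",
                            "name": "ill",
                            "states": ["episode"],
                            "resources": {},
                        },
                    },
                ],
            }
        },
        "Certain": {
            "root": {
                "kind": "terminal",
                "name": "treated",
                "states": ["maintenance"],
                "resources": {"gp_plan": "1"},
            }
        },
    }
    return ModelConfig(
        strategy_names=("Gamble", "Certain"),
        cycle_length_weeks=7,
        n_cycles=1,
        wtp_default=52000.0 / 7.0,
        proportion_moderate=0.688,
        proportion_mild=0.312,
        psa_iterations=1000,
        rng_seed=7,
        wtp_grid=(0.0, 52000.0 / 7.0, 20000.0),
        parameters=parameters,
        topology=topology,
    )


@pytest.fixture
def toy_config() -> ModelConfig:
    return two_arm_toy_config()
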