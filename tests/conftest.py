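"""Shared fixtures: presets and hand-built toy parameter sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from fabrycea import ParameterSet, generate_parameter_preset
from fabrycea.parameters import LifeTable, ProbabilityEstimate, UtilityEstimate
from fabrycea.states import STATES, Cluster, State, GRAPH, TRANSPLANT_EDGE


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return generate_parameter_preset("base")


@pytest.fixture(scope="session")
def classical_params() -> ParameterSet:
    return generate_parameter_preset("classical")


@pytest.fixture(scope="session")
def null_params() -> ParameterSet:
    return generate_parameter_preset("null-effect")


def zero_life_table(max_age: int = 100) -> LifeTable:
    rows = [
        (age, sex, 0.0) for age in range(max_age + 1) for sex in ("male", "female")
    ]
    return LifeTable(pd.DataFrame(rows, columns=["age", "sex", "qx"]))


def make_toy_params(
    transition_ps: dict | None = None,
    death_any: float = 0.0,
    death_per_state: dict | None = None,
    qx: float = 0.0,
    utility: float = 1.0,
    cluster_costs: dict | None = None,
    **overrides,
) -> ParameterSet:
    """A fully-specified parameter set with simple, controllable numbers.

    ``transition_ps`` maps (State, State) edges to a shared annual
    probability; unlisted edges get 0.  All four alive clusters share
    ``utility`` unless a dict is passed.
    """
    transition_ps = transition_ps or {}
    edges = GRAPH.progression_edges() + [TRANSPLANT_EDGE]
    transitions = {
        edge: {
            sex: ProbabilityEstimate(p=float(transition_ps.get(edge, 0.0)))
            for sex in ("male", "female")
        }
        for edge in edges
    }
    death = {
        None: {
            sex: ProbabilityEstimate(p=death_any) for sex in ("male", "female")
        }
    }
    for state, p in (death_per_state or {}).items():
        death[state] = {sex: ProbabilityEstimate(p=p) for sex in ("male", "female")}
    utilities = (
        {c: UtilityEstimate(mean=utility[c]) for c in utility}
        if isinstance(utility, dict)
        else {
            c: UtilityEstimate(mean=utility)
            for c in Cluster
            if c is not Cluster.DEAD
        }
    )
    costs = cluster_costs or {
        c: 0.0 for c in Cluster if c is not Cluster.DEAD
    }
    rows = [
        (age, sex, qx) for age in range(101) for sex in ("male", "female")
    ]
    lt = LifeTable(pd.DataFrame(rows, columns=["age", "sex", "qx"]))
    params = ParameterSet(
        transitions=transitions,
        death=death,
        utilities=utilities,
        cost_cluster=dict(costs),
        life_table=lt,
        **overrides,
    )
    params.validate()
    return params


@pytest.fixture
def toy_immortal() -> ParameterSet:
    """Nobody progresses, nobody dies: 70 asymptomatic years."""
    return make_toy_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130219)
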