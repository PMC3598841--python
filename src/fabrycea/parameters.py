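"""Parameter containers, parameter-file loading and transition-matrix assembly.

A :class:`ParameterSet` bundles everything one model run needs: annual
transition probabilities by sex with optional 95% confidence limits and beta
shape parameters, per-cluster health utilities and annual costs, the two
treatment-effect odds ratios with their median treatment durations, discount
rates, the ERT drug price, a general-population life table and simulation
settings.

Parameter files are YAML documents with sections ``transitions``,
``utilities``, ``costs``, ``treatment_effect``, ``discounting`` and
``simulation`` (an optional ``states`` section may restate the state list and
is checked against the model).  A machine-readable schema of the layout is
shipped as ``data/parameterset.schema.json``; the loader enforces the same
rules directly.

Mortality: the model carries a (possibly state-specific) annual death
probability estimated from the cohort, floored by the general-population
death probability for the patient's current age and sex — whenever the
cohort-based probability of dying falls below the population's, the
population value is used.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .states import (
    CLUSTER_OF,
    FIRST_COMPLICATION_EDGES,
    GRAPH,
    N_STATES,
    SECOND_COMPLICATION_EDGES,
    STATE_INDEX,
    STATES,
    TRANSPLANT_EDGE,
    Cluster,
    State,
    TransitionGraph,
    edge_key,
    parse_edge,
)
from .treatment import TreatmentEffect

SEXES: Tuple[str, str] = ("male", "female")

_ALIVE_CLUSTERS: Tuple[Cluster, ...] = (
    Cluster.ASYMPTOMATIC,
    Cluster.ACRO_OR_SYMPTOMS,
    Cluster.SINGLE_COMPLICATION,
    Cluster.MULTIPLE_COMPLICATIONS,
)


class ConfigurationError(ValueError):
    """A parameter file is structurally incomplete or inconsistent."""


class ParameterError(ValueError):
    """Parameter values are out of range or mutually incompatible."""


def beta_shapes_from_mean_sd(mean: float, sd: float) -> Tuple[float, float]:
    """Method-of-moments beta shape parameters for a given mean and SD.

    Returns ``(nan, nan)`` for a degenerate (zero-variance) distribution.
    """
    if not 0.0 < mean < 1.0 or sd <= 0.0:
        return (math.nan, math.nan)
    var = sd * sd
    max_var = mean * (1.0 - mean)
    if var >= max_var:
        var = 0.999 * max_var
    nu = mean * (1.0 - mean) / var - 1.0
    return (mean * nu, (1.0 - mean) * nu)


@dataclass(frozen=True)
class ProbabilityEstimate:
    """An annual probability with optional CI and beta shape parameters."""

    p: float
    lcl: Optional[float] = None
    ucl: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    median_unreached: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"probability {self.p} outside [0, 1]")
        if self.lcl is not None and self.ucl is not None:
            if not 0.0 <= self.lcl <= self.ucl <= 1.0:
                raise ParameterError(
                    f"confidence limits ({self.lcl}, {self.ucl}) invalid"
                )

    def with_beta_from_ci(self) -> "ProbabilityEstimate":
        """Fill beta shapes from the CI width (normal-approximation SD)."""
        if self.alpha is not None or self.lcl is None or self.ucl is None:
            return self
        sd = (self.ucl - self.lcl) / (2 * 1.959963984540054)
        a, b = beta_shapes_from_mean_sd(self.p, sd)
        if math.isnan(a):
            return self
        return replace(self, alpha=a, beta=b)

    @property
    def degenerate(self) -> bool:
        return self.alpha is None or self.beta is None

    def sample(self, rng: np.random.Generator) -> float:
        """One second-order draw; degenerate estimates return the point value."""
        if self.degenerate:
            return self.p
        return float(rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class UtilityEstimate:
    mean: float
    lcl: Optional[float] = None
    ucl: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ParameterError(f"utility {self.mean} outside [0, 1]")


class LifeTable:
    """General-population annual death probabilities ``qx`` by age and sex.

    Backed by a ``age,sex,qx`` table; ages in whole years, qx in [0, 1].
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"age", "sex", "qx"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(
                f"life table must have columns {sorted(required)}"
            )
        if ((frame["qx"] < 0) | (frame["qx"] > 1)).any():
            raise ParameterError("life-table qx outside [0, 1]")
        self._qx: Dict[Tuple[int, str], float] = {
            (int(r.age), str(r.sex)): float(r.qx) for r in frame.itertuples()
        }
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    @classmethod
    def bundled(cls) -> "LifeTable":
        """The synthetic Dutch-style life table shipped with the package."""
        ref = resources.files("fabrycea.data") / "life_table_synthetic_nl.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def qx(self, age: int, sex: str) -> float:
        try:
            return self._qx[(int(age), sex)]
        except KeyError:
            raise ParameterError(
                f"life table has no entry for age {age}, sex {sex!r}"
            ) from None

    def covers(self, ages: Iterable[int], sexes: Iterable[str] = SEXES) -> bool:
        return all((a, s) in self._qx for a in ages for s in sexes)


def apply_mortality_floor(
    p_model: float, age: int, sex: str, life_table: LifeTable
) -> float:
    """Floor a model death probability by the general-population one.

    Returns ``max(p_model, qx(age, sex))``; idempotent by construction.
    """
    if not 0.0 <= p_model <= 1.0:
        raise ParameterError(f"death probability {p_model} outside [0, 1]")
    return max(p_model, life_table.qx(age, sex))


@dataclass
class ParameterSet:
    """All inputs of one model configuration.

    ``transitions`` holds untreated annual probabilities per progression edge
    (and the transplant return edge) by sex.  ``death`` holds the cohort-based
    annual death probability, either globally (key ``None``) or per state;
    the life-table floor applies on top in either case.  Treated
    probabilities are derived, not stored: the first-complication odds ratio
    acts on the symptoms -> single-complication edges and the
    second-complication odds ratio on the single -> double edges.
    """

    transitions: Dict[Tuple[State, State], Dict[str, ProbabilityEstimate]]
    death: Dict[Optional[State], Dict[str, ProbabilityEstimate]]
    utilities: Dict[Cluster, UtilityEstimate]
    cost_cluster: Dict[Cluster, float]
    cost_state_overrides: Dict[State, float] = field(default_factory=dict)
    cost_production_loss: Dict[Cluster, float] = field(default_factory=dict)
    cost_ert: float = 200_000.0
    unit_cost_hour: float = 30.0
    or_first: float = 0.82
    or_first_ci: Tuple[float, float] = (0.68, 0.96)
    or_second: float = 0.52
    or_second_ci: Tuple[float, float] = (0.31, 0.88)
    median_duration_symptoms: float = 5.0
    median_duration_single: float = 5.0
    discount_rate_effects: float = 0.0
    discount_rate_costs: float = 0.0
    horizon: int = 70
    cycle_length: float = 1.0
    sex_mix: float = 0.5
    ert_start_rule: str = "at-symptoms"
    wtp_grid: Tuple[float, ...] = ()
    life_table: LifeTable = field(default_factory=LifeTable.bundled)
    graph: TransitionGraph = field(default_factory=lambda: GRAPH)
    utility_offset_untreated: float = 0.0  # scenario 2 lever
    include_production_loss: bool = False  # scenario 6 lever
    comparator_first_rrr: bool = False  # scenario 4 lever (ACE-ARB arm)
    metadata: Dict[str, object] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for edge in self.graph.progression_edges() + [TRANSPLANT_EDGE]:
            for sex in SEXES:
                if sex not in self.transitions.get(edge, {}):
                    raise ConfigurationError(
                        f"missing untreated probability for edge "
                        f"{edge_key(*edge)}, sex {sex!r}"
                    )
        if None not in self.death and not all(
            s in self.death for s in STATES if s is not State.DEATH
        ):
            raise ConfigurationError(
                "death section needs an 'any' entry or one entry per state"
            )
        for cl in _ALIVE_CLUSTERS:
            if cl not in self.utilities:
                raise ConfigurationError(f"missing utility for cluster {cl.value}")
            if cl not in self.cost_cluster:
                raise ConfigurationError(f"missing annual cost for cluster {cl.value}")
        if any(c < 0 for c in self.cost_cluster.values()):
            raise ParameterError("negative state cost")
        if any(c < 0 for c in self.cost_state_overrides.values()):
            raise ParameterError("negative state cost")
        if self.cost_ert < 0 or self.unit_cost_hour < 0:
            raise ParameterError("negative cost")
        if self.or_first <= 0 or self.or_second <= 0:
            raise ParameterError("odds ratios must be positive")
        if not 0.0 <= self.sex_mix <= 1.0:
            raise ParameterError("sex_mix must lie in [0, 1]")
        if not self.life_table.covers(range(self.horizon + 1)):
            raise ConfigurationError(
                f"life table does not cover ages 0..{self.horizon} for both sexes"
            )

    # -- derived quantities -------------------------------------------------

    def effect_for_edge(self, edge: Tuple[State, State]) -> Optional[TreatmentEffect]:
        if edge in FIRST_COMPLICATION_EDGES:
            return TreatmentEffect(self.or_first, self.median_duration_symptoms)
        if edge in SECOND_COMPLICATION_EDGES:
            return TreatmentEffect(self.or_second, self.median_duration_single)
        return None

    def probability(
        self, edge: Tuple[State, State], sex: str, treated: bool
    ) -> float:
        """Annual probability for a progression/transplant edge."""
        try:
            p = self.transitions[edge][sex].p
        except KeyError:
            raise ConfigurationError(
                f"missing probability for edge {edge_key(*edge)}, sex {sex!r}"
            ) from None
        effect = self.effect_for_edge(edge) if treated else None
        if effect is None or p in (0.0, 1.0):
            return p
        return effect.treated_probability(p)

    def death_probability(self, state: State, sex: str, age: int) -> float:
        est = self.death.get(state) or self.death.get(None)
        if est is None or sex not in est:
            raise ConfigurationError(
                f"missing death probability for state {state.value}, sex {sex!r}"
            )
        return apply_mortality_floor(est[sex].p, age, sex, self.life_table)

    def utility(self, cluster: Cluster) -> float:
        if cluster is Cluster.DEAD:
            return 0.0
        try:
            return self.utilities[cluster].mean
        except KeyError:
            raise ConfigurationError(
                f"missing utility for cluster {cluster.value}"
            ) from None

    def annual_cost(self, state: State) -> float:
        if state is State.DEATH:
            return 0.0
        if state in self.cost_state_overrides:
            return self.cost_state_overrides[state]
        return self.cost_cluster[CLUSTER_OF[state]]

    def production_loss(self, state: State) -> float:
        if state is State.DEATH:
            return 0.0
        return self.cost_production_loss.get(CLUSTER_OF[state], 0.0)

    # -- matrix assembly ----------------------------------------------------

    def transition_matrix(
        self,
        sex: str,
        treated,
        age: int,
        comparator_first_rrr: Optional[bool] = None,
    ) -> np.ndarray:
        """Row-stochastic annual transition matrix over the 11 states.

        ``treated`` is either a flag applied to every state or a predicate
        ``state -> bool`` (strategies treat only part of the state space).
        Residual probability stays on the diagonal; the death column is the
        floored death probability; the death row is the identity row.
        """
        if callable(treated):
            is_treated = treated
        else:
            is_treated = lambda s, _t=bool(treated): _t  # noqa: E731
        arb = self.comparator_first_rrr if comparator_first_rrr is None else comparator_first_rrr
        P = np.zeros((N_STATES, N_STATES))
        for s in STATES:
            i = STATE_INDEX[s]
            if s is State.DEATH:
                P[i, i] = 1.0
                continue
            p_death = self.death_probability(s, sex, age)
            P[i, STATE_INDEX[State.DEATH]] = p_death
            exit_sum = p_death
            for t in self.graph.successors(s):
                if t is State.DEATH:
                    continue
                edge = (s, t)
                p = self.probability(edge, sex, is_treated(s))
                if (
                    arb
                    and not is_treated(s)
                    and edge in FIRST_COMPLICATION_EDGES
                ):
                    # comparator arm on ACE-ARB: same first-complication risk
                    # reduction as the treated arm
                    p = self.probability(edge, sex, True)
                P[i, STATE_INDEX[t]] = p
                exit_sum += p
            if exit_sum > 1.0 + 1e-12:
                raise ParameterError(
                    f"exit probabilities from {s.value} sum to {exit_sum:.6f} > 1 "
                    f"(sex {sex!r}, age {age})"
                )
            P[i, i] = max(0.0, 1.0 - exit_sum)
        return P

    # -- PSA sampling -------------------------------------------------------

    def sample_transition_probabilities(
        self, rng: np.random.Generator
    ) -> "ParameterSet":
        """One second-order draw of every beta-distributed transition probability."""
        new_tr = {
            edge: {
                sex: replace(est, p=est.sample(rng))
                for sex, est in by_sex.items()
            }
            for edge, by_sex in self.transitions.items()
        }
        new_death = {
            key: {
                sex: replace(est, p=est.sample(rng))
                for sex, est in by_sex.items()
            }
            for key, by_sex in self.death.items()
        }
        return replace(self, transitions=new_tr, death=new_death)

    # -- provenance ---------------------------------------------------------

    def content_hash(self) -> str:
        """Stable short hash of the numeric content, for run metadata."""
        payload = {
            "transitions": {
                edge_key(*e): {s: est.p for s, est in by_sex.items()}
                for e, by_sex in sorted(
                    self.transitions.items(),
                    key=lambda kv: (STATE_INDEX[kv[0][0]], STATE_INDEX[kv[0][1]]),
                )
            },
            "death": {
                (k.value if k else "any"): {s: est.p for s, est in by_sex.items()}
                for k, by_sex in self.death.items()
            },
            "utilities": {c.value: u.mean for c, u in self.utilities.items()},
            "costs": {c.value: v for c, v in self.cost_cluster.items()},
            "cost_ert": self.cost_ert,
            "or": [self.or_first, self.or_second],
            "durations": [self.median_duration_symptoms, self.median_duration_single],
            "discount": [self.discount_rate_effects, self.discount_rate_costs],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# -- parameter-file loading -------------------------------------------------


def _as_prob(value) -> ProbabilityEstimate:
    if isinstance(value, Mapping):
        est = ProbabilityEstimate(
            p=float(value["p"]),
            lcl=float(value["lcl"]) if "lcl" in value else None,
            ucl=float(value["ucl"]) if "ucl" in value else None,
            alpha=float(value["alpha"]) if "alpha" in value else None,
            beta=float(value["beta"]) if "beta" in value else None,
            median_unreached=bool(value.get("median_unreached", False)),
        )
    else:
        est = ProbabilityEstimate(p=float(value))
    return est.with_beta_from_ci()


def _by_sex(value) -> Dict[str, ProbabilityEstimate]:
    if isinstance(value, Mapping) and set(value) & set(SEXES):
        out = {sex: _as_prob(value[sex]) for sex in SEXES if sex in value}
        if set(out) != set(SEXES):
            missing = set(SEXES) - set(out)
            raise ConfigurationError(f"missing sexes {sorted(missing)}")
        return out
    est = _as_prob(value)
    return {sex: est for sex in SEXES}


def parameter_set_from_dict(
    doc: Mapping, life_table: Optional[LifeTable] = None
) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a parsed parameter file."""
    for section in ("transitions", "utilities", "costs", "treatment_effect", "simulation"):
        if section not in doc:
            raise ConfigurationError(f"parameter file missing section [{section}]")
    if "states" in doc:
        declared = [State(s) for s in doc["states"]]
        if set(declared) != set(STATES):
            raise ConfigurationError("states section does not match the model")

    transitions: Dict[Tuple[State, State], Dict[str, ProbabilityEstimate]] = {}
    death: Dict[Optional[State], Dict[str, ProbabilityEstimate]] = {}
    for key, value in doc["transitions"].items():
        if key == "death":
            for dkey, dval in value.items():
                state = None if dkey == "any" else State(dkey)
                death[state] = _by_sex(dval)
            continue
        edge = parse_edge(key)
        if edge not in GRAPH:
            raise ConfigurationError(f"transition {key!r} is not a model edge")
        transitions[edge] = _by_sex(value)

    utilities = {
        Cluster(name): (
            UtilityEstimate(**value)
            if isinstance(value, Mapping)
            else UtilityEstimate(mean=float(value))
        )
        for name, value in doc["utilities"].items()
    }

    costs = doc["costs"]
    cost_cluster = {Cluster(k): float(v) for k, v in costs.get("state", {}).items()}
    overrides = {State(k): float(v) for k, v in costs.get("state_overrides", {}).items()}
    production = {Cluster(k): float(v) for k, v in costs.get("production_loss", {}).items()}

    te = doc["treatment_effect"]

    def _or(entry) -> Tuple[float, Tuple[float, float]]:
        if isinstance(entry, Mapping):
            return float(entry["value"]), (
                float(entry.get("lcl", entry["value"])),
                float(entry.get("ucl", entry["value"])),
            )
        return float(entry), (float(entry), float(entry))

    or_first, or_first_ci = _or(te["or_first"])
    or_second, or_second_ci = _or(te["or_second"])

    disc = doc.get("discounting", {})
    sim = doc["simulation"]
    wtp = sim.get("wtp_grid")
    if wtp is None:
        lo = float(sim.get("wtp_min", 20_000))
        hi = float(sim.get("wtp_max", 10_000_000))
        n = int(sim.get("wtp_points", 25))
        wtp = np.logspace(math.log10(lo), math.log10(hi), n).tolist()

    if life_table is None:
        lt_path = sim.get("life_table")
        life_table = LifeTable.from_csv(lt_path) if lt_path else LifeTable.bundled()

    params = ParameterSet(
        transitions=transitions,
        death=death,
        utilities=utilities,
        cost_cluster=cost_cluster,
        cost_state_overrides=overrides,
        cost_production_loss=production,
        cost_ert=float(costs.get("ert_per_year", 200_000)),
        unit_cost_hour=float(costs.get("unit_cost_hour", 30)),
        or_first=or_first,
        or_first_ci=or_first_ci,
        or_second=or_second,
        or_second_ci=or_second_ci,
        median_duration_symptoms=float(te.get("median_duration_symptoms", 5.0)),
        median_duration_single=float(te.get("median_duration_single_complication", 5.0)),
        discount_rate_effects=float(disc.get("effects", 0.0)),
        discount_rate_costs=float(disc.get("costs", 0.0)),
        horizon=int(sim.get("horizon", 70)),
        cycle_length=float(sim.get("cycle_length", 1.0)),
        sex_mix=float(sim.get("sex_mix", 0.5)),
        ert_start_rule=str(sim.get("ert_start_rule", "at-symptoms")),
        wtp_grid=tuple(float(w) for w in wtp),
        life_table=life_table,
        metadata=dict(doc.get("metadata", {})),
    )
    params.validate()
    return params


def load_parameter_file(
    path: str | Path, life_table: Optional[LifeTable] = None
) -> ParameterSet:
    """Load, validate and return a :class:`ParameterSet` from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: not a mapping document")
    return parameter_set_from_dict(doc, life_table=life_table)


def build_transition_matrix(
    params: ParameterSet, sex: str, treated, age: int
) -> np.ndarray:
    """Module-level convenience wrapper over ``ParameterSet.transition_matrix``."""
    return params.transition_matrix(sex, treated, age)
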