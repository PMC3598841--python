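"""Lifetime simulation engine: deterministic cohort trace and microsimulation.

A cohort enters the model asymptomatic at birth and is advanced through 70
one-year cycles (to age 70 or death).  Each cycle the annual transition
matrix is assembled for the patient's current age (which sets the
general-population mortality floor) and the strategy's treatment status per
state, occupancy is advanced, and outcomes are accrued from the
post-transition occupancy:

* life-years and years free of end-organ damage (YFEOD: time spent
  asymptomatic, with acroparesthesia, or symptomatic);
* QALYs: occupancy weighted by the per-cluster health utility (death = 0);
* costs: per-state annual health-care costs, the ERT drug cost for treated
  occupancy, and optionally production-loss costs from age 18.

Accruals are kept both undiscounted and discounted (effects and costs at
their own annual rates; the first model year is undiscounted).  No
half-cycle correction is applied (switchable via ``half_cycle``).

The microsimulation draws individual state paths from the same matrices and
converges to the cohort expectation as the number of simulated patients
grows; with a fixed seed it is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .parameters import SEXES, ParameterSet
from .states import (
    CLUSTER_OF,
    N_STATES,
    STATE_INDEX,
    STATES,
    YFEOD_STATES,
    Cluster,
    State,
)

__all__ = [
    "Strategy",
    "CohortTrace",
    "ArmOutcome",
    "CEResult",
    "discount_factor",
    "run_cohort",
    "run_microsim",
    "evaluate_strategy",
    "compare_strategies",
    "accrue_yfeod",
    "accrue_qalys",
    "accrue_costs",
]

_YFEOD_IDX = np.array([STATE_INDEX[s] for s in YFEOD_STATES])
_DEATH_IDX = STATE_INDEX[State.DEATH]
_ALIVE_IDX = np.array([STATE_INDEX[s] for s in STATES if s is not State.DEATH])

#: States in which ERT can be given (symptomatic stage onward).
_SYMPTOMATIC_ONWARD = frozenset(
    s
    for s in STATES
    if s not in (State.ASYMPTOMATIC, State.ACROPARESTHESIA, State.DEATH)
)
_AT_MOST_ONE_COMPLICATION = frozenset(
    {State.SYMPTOMS, State.ESRD, State.CARDIAC, State.CVA}
)


@dataclass(frozen=True)
class Strategy:
    """A named treatment rule: a predicate over (state, age).

    Treatment is a deterministic function of the current state and age, in
    line with the memoryless model: ``no_ert`` never treats; ``ert_at_symptoms``
    treats every state from the symptomatic stage onward; ``ert_at_40``
    additionally requires age >= 40; ``ert_stop_after_2`` treats only up to
    one complication.  Death is never treated.
    """

    name: str
    predicate: Callable[[State, int], bool]

    def treats(self, state: State, age: int) -> bool:
        if state is State.DEATH:
            return False
        return bool(self.predicate(state, age))

    @staticmethod
    def no_ert() -> "Strategy":
        return Strategy("no_ert", lambda s, a: False)

    @staticmethod
    def ert_at_symptoms() -> "Strategy":
        return Strategy("ert_at_symptoms", lambda s, a: s in _SYMPTOMATIC_ONWARD)

    @staticmethod
    def ert_at_40() -> "Strategy":
        return Strategy(
            "ert_at_40", lambda s, a: s in _SYMPTOMATIC_ONWARD and a >= 40
        )

    @staticmethod
    def ert_stop_after_2() -> "Strategy":
        return Strategy(
            "ert_stop_after_2", lambda s, a: s in _AT_MOST_ONE_COMPLICATION
        )

    @staticmethod
    def from_rule(rule: str) -> "Strategy":
        table = {
            "never": Strategy.no_ert,
            "no_ert": Strategy.no_ert,
            "at-symptoms": Strategy.ert_at_symptoms,
            "ert_at_symptoms": Strategy.ert_at_symptoms,
            "at-age-40": Strategy.ert_at_40,
            "ert_at_40": Strategy.ert_at_40,
            "stop-after-2-complications": Strategy.ert_stop_after_2,
            "ert_stop_after_2": Strategy.ert_stop_after_2,
        }
        try:
            return table[rule]()
        except KeyError:
            raise ValueError(f"unknown ERT start rule {rule!r}") from None


def discount_factor(rate: float, cycle_index: int) -> float:
    """Discount factor ``1/(1+rate)**t`` with t = 0 for the first model year."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle_index < 0:
        raise ValueError("cycle index must be non-negative")
    return 1.0 / (1.0 + rate) ** cycle_index


@dataclass
class CohortTrace:
    """State occupancy per cycle plus per-cycle accruals for one run.

    ``occupancy[t]`` is the distribution after ``t`` cycles (row 0 is the
    initial distribution); accrual arrays have one entry per cycle and are
    computed from the post-transition occupancy of that cycle.
    """

    strategy: str
    sex: str
    occupancy: np.ndarray  # (horizon+1, 11)
    life_years: np.ndarray
    yfeod: np.ndarray
    qalys: np.ndarray
    cost_state: np.ndarray
    cost_drug: np.ndarray
    cost_production: np.ndarray
    effect_discount: np.ndarray  # per-cycle factors
    cost_discount: np.ndarray

    def _total(self, per_cycle: np.ndarray, discounted: bool, factors: np.ndarray) -> float:
        return float((per_cycle * factors).sum() if discounted else per_cycle.sum())

    def total_life_years(self, discounted: bool = False) -> float:
        return self._total(self.life_years, discounted, self.effect_discount)

    def total_yfeod(self, discounted: bool = False) -> float:
        return self._total(self.yfeod, discounted, self.effect_discount)

    def total_qalys(self, discounted: bool = False) -> float:
        return self._total(self.qalys, discounted, self.effect_discount)

    def total_cost(self, discounted: bool = False, production: bool = False) -> float:
        per_cycle = self.cost_state + self.cost_drug
        if production:
            per_cycle = per_cycle + self.cost_production
        return self._total(per_cycle, discounted, self.cost_discount)

    def total_drug_cost(self, discounted: bool = False) -> float:
        return self._total(self.cost_drug, discounted, self.cost_discount)

    def to_frame(self):
        import pandas as pd

        data = {f"occ_{s.value}": self.occupancy[1:, STATE_INDEX[s]] for s in STATES}
        data.update(
            cycle=np.arange(len(self.life_years)),
            life_years=self.life_years,
            yfeod=self.yfeod,
            qalys=self.qalys,
            cost_state=self.cost_state,
            cost_drug=self.cost_drug,
            cost_production=self.cost_production,
        )
        return pd.DataFrame(data)


def _utility_vector(params: ParameterSet, utility_offset: float) -> np.ndarray:
    u = np.zeros(N_STATES)
    for s in STATES:
        if s is State.DEATH:
            continue
        u[STATE_INDEX[s]] = max(0.0, params.utility(CLUSTER_OF[s]) - utility_offset)
    return u


def _cost_vector(params: ParameterSet) -> np.ndarray:
    return np.array([params.annual_cost(s) for s in STATES])


def _production_vector(params: ParameterSet) -> np.ndarray:
    return np.array([params.production_loss(s) for s in STATES])


def _treated_mask(strategy: Strategy, age: int) -> np.ndarray:
    return np.array([strategy.treats(s, age) for s in STATES])


def cycle_matrices(
    params: ParameterSet, strategy: Strategy, sex: str
) -> np.ndarray:
    """Annual transition matrices for every cycle (age) of the horizon."""
    mats = np.empty((params.horizon, N_STATES, N_STATES))
    for t in range(params.horizon):
        mats[t] = params.transition_matrix(
            sex, lambda s, _t=t: strategy.treats(s, _t), t
        )
    return mats


def run_cohort(
    params: ParameterSet,
    strategy: Strategy,
    sex: str,
    utility_offset: float = 0.0,
    half_cycle: bool = False,
    matrices: Optional[np.ndarray] = None,
) -> CohortTrace:
    """Deterministic lifetime cohort trace for one sex and strategy.

    ``utility_offset`` subtracts a constant from every alive cluster utility
    (floored at zero) — the lever for the lower-quality-of-life-untreated
    scenario.  Production-loss costs are accrued only for cycles at ages >=
    18 and only enter totals when requested.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    horizon = params.horizon
    u_vec = _utility_vector(params, utility_offset)
    c_vec = _cost_vector(params)
    pl_vec = _production_vector(params)

    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0, STATE_INDEX[State.ASYMPTOMATIC]] = 1.0
    life_years = np.zeros(horizon)
    yfeod = np.zeros(horizon)
    qalys = np.zeros(horizon)
    cost_state = np.zeros(horizon)
    cost_drug = np.zeros(horizon)
    cost_production = np.zeros(horizon)

    cl = params.cycle_length
    for t in range(horizon):
        P = (
            matrices[t]
            if matrices is not None
            else params.transition_matrix(
                sex, lambda s, _t=t: strategy.treats(s, _t), t
            )
        )
        row_sums = P.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise RuntimeError(f"non-stochastic transition matrix at cycle {t}")
        occ_next = occupancy[t] @ P
        occupancy[t + 1] = occ_next
        basis = 0.5 * (occupancy[t] + occ_next) if half_cycle else occ_next
        treated = _treated_mask(strategy, t)
        life_years[t] = basis[_ALIVE_IDX].sum() * cl
        yfeod[t] = basis[_YFEOD_IDX].sum() * cl
        qalys[t] = float(basis @ u_vec) * cl
        cost_state[t] = float(basis @ c_vec) * cl
        cost_drug[t] = float(basis[treated].sum()) * params.cost_ert * cl
        if t >= 18:
            cost_production[t] = float(basis @ pl_vec) * cl

    effect_disc = np.array(
        [discount_factor(params.discount_rate_effects, t) for t in range(horizon)]
    )
    cost_disc = np.array(
        [discount_factor(params.discount_rate_costs, t) for t in range(horizon)]
    )
    return CohortTrace(
        strategy=strategy.name,
        sex=sex,
        occupancy=occupancy,
        life_years=life_years,
        yfeod=yfeod,
        qalys=qalys,
        cost_state=cost_state,
        cost_drug=cost_drug,
        cost_production=cost_production,
        effect_discount=effect_disc,
        cost_discount=cost_disc,
    )


# -- accrual helpers (operate on an existing trace) -------------------------


def accrue_yfeod(trace: CohortTrace, discounted: bool = False) -> float:
    """Lifetime years free of end-organ damage, recomputed from occupancy.

    Sums post-transition occupancy of the asymptomatic, acroparesthesia and
    symptomatic states over all cycles (times the cycle length), applying
    the trace's effect discount factors when requested.
    """
    per_cycle = trace.occupancy[1:, _YFEOD_IDX].sum(axis=1)
    factors = trace.effect_discount if discounted else 1.0
    return float((per_cycle * factors).sum())


def accrue_qalys(
    trace: CohortTrace,
    utilities: Dict[Cluster, float],
    discounted: bool = False,
) -> float:
    """Lifetime QALYs recomputed from occupancy and per-cluster utilities.

    Death contributes zero; a missing alive-cluster utility is an error.
    """
    u = np.zeros(N_STATES)
    for s in STATES:
        if s is State.DEATH:
            continue
        cl = CLUSTER_OF[s]
        if cl not in utilities:
            raise KeyError(f"missing utility for cluster {cl.value}")
        u[STATE_INDEX[s]] = utilities[cl]
    per_cycle = trace.occupancy[1:] @ u
    factors = trace.effect_discount if discounted else 1.0
    return float((per_cycle * factors).sum())


def accrue_costs(
    trace: CohortTrace,
    params: ParameterSet,
    strategy: Strategy,
    discounted: bool = False,
    production: bool = False,
) -> float:
    """Lifetime costs recomputed from occupancy: per-state annual costs plus
    the ERT price over treated occupancy, optionally adding production-loss
    costs for cycles at ages >= 18."""
    c_vec = _cost_vector(params)
    if np.any(c_vec < 0):
        raise ValueError("negative cost in table")
    pl_vec = _production_vector(params)
    horizon = trace.occupancy.shape[0] - 1
    per_cycle = np.empty(horizon)
    for t in range(horizon):
        occ = trace.occupancy[t + 1]
        treated = _treated_mask(strategy, t)
        total = float(occ @ c_vec) + float(occ[treated].sum()) * params.cost_ert
        if production and t >= 18:
            total += float(occ @ pl_vec)
        per_cycle[t] = total
    factors = trace.cost_discount if discounted else 1.0
    return float((per_cycle * factors).sum())


# -- outcome containers -----------------------------------------------------


@dataclass(frozen=True)
class ArmOutcome:
    """Lifetime outcomes of one strategy (one sex or the sex mix)."""

    strategy: str
    yfeod: float
    yfeod_disc: float
    qalys: float
    qalys_disc: float
    life_years: float
    life_years_disc: float
    cost: float
    cost_disc: float
    drug_cost: float
    drug_cost_disc: float

    @staticmethod
    def mix(a: "ArmOutcome", b: "ArmOutcome", weight_a: float) -> "ArmOutcome":
        w, v = weight_a, 1.0 - weight_a
        return ArmOutcome(
            strategy=a.strategy,
            **{
                f: w * getattr(a, f) + v * getattr(b, f)
                for f in (
                    "yfeod", "yfeod_disc", "qalys", "qalys_disc",
                    "life_years", "life_years_disc",
                    "cost", "cost_disc", "drug_cost", "drug_cost_disc",
                )
            },
        )


def _outcome_from_trace(trace: CohortTrace, production: bool) -> ArmOutcome:
    return ArmOutcome(
        strategy=trace.strategy,
        yfeod=trace.total_yfeod(False),
        yfeod_disc=trace.total_yfeod(True),
        qalys=trace.total_qalys(False),
        qalys_disc=trace.total_qalys(True),
        life_years=trace.total_life_years(False),
        life_years_disc=trace.total_life_years(True),
        cost=trace.total_cost(False, production),
        cost_disc=trace.total_cost(True, production),
        drug_cost=trace.total_drug_cost(False),
        drug_cost_disc=trace.total_drug_cost(True),
    )


def evaluate_strategy(
    params: ParameterSet,
    strategy: Strategy,
    utility_offset: float = 0.0,
    comparator_first_rrr: bool = False,
) -> Dict[str, ArmOutcome]:
    """Cohort outcomes per sex plus the sex-mix combination ("all")."""
    production = params.include_production_loss
    outcomes: Dict[str, ArmOutcome] = {}
    for sex in SEXES:
        mats = np.empty((params.horizon, N_STATES, N_STATES))
        for t in range(params.horizon):
            mats[t] = params.transition_matrix(
                sex,
                lambda s, _t=t: strategy.treats(s, _t),
                t,
                comparator_first_rrr=comparator_first_rrr,
            )
        trace = run_cohort(
            params, strategy, sex, utility_offset=utility_offset, matrices=mats
        )
        outcomes[sex] = _outcome_from_trace(trace, production)
    outcomes["all"] = ArmOutcome.mix(
        outcomes["male"], outcomes["female"], params.sex_mix
    )
    return outcomes


@dataclass(frozen=True)
class Delta:
    """Incremental outcomes of the active strategy versus the comparator."""

    yfeod: float
    qalys: float
    life_years: float
    cost: float


@dataclass
class CEResult:
    """Lifetime cost-effectiveness comparison of two strategies.

    Holds per-arm outcomes by sex and overall, incremental effects/costs and
    the ICERs per YFEOD and per QALY, in discounted and undiscounted form.
    """

    active: Dict[str, ArmOutcome]
    comparator: Dict[str, ArmOutcome]

    def delta(self, group: str = "all", discounted: bool = False) -> Delta:
        a, c = self.active[group], self.comparator[group]
        sfx = "_disc" if discounted else ""
        return Delta(
            yfeod=getattr(a, "yfeod" + sfx) - getattr(c, "yfeod" + sfx),
            qalys=getattr(a, "qalys" + sfx) - getattr(c, "qalys" + sfx),
            life_years=getattr(a, "life_years" + sfx) - getattr(c, "life_years" + sfx),
            cost=getattr(a, "cost" + sfx) - getattr(c, "cost" + sfx),
        )

    def icer(self, outcome: str = "qalys", group: str = "all", discounted: bool = False):
        from .economics import icer as _icer

        d = self.delta(group, discounted)
        return _icer(d.cost, getattr(d, outcome))


def compare_strategies(
    params: ParameterSet,
    active: Strategy,
    comparator: Optional[Strategy] = None,
    utility_offset_comparator: float = 0.0,
    comparator_first_rrr: bool = False,
) -> CEResult:
    """Run both arms and assemble a :class:`CEResult`.

    ``utility_offset_comparator`` lowers the comparator arm's utilities (the
    lower-QoL-untreated scenario); ``comparator_first_rrr`` grants the
    comparator arm the first-complication risk reduction (the ACE-ARB
    scenario)."""
    comparator = comparator or Strategy.no_ert()
    active_out = evaluate_strategy(params, active)
    comp_out = evaluate_strategy(
        params,
        comparator,
        utility_offset=utility_offset_comparator,
        comparator_first_rrr=comparator_first_rrr,
    )
    return CEResult(active=active_out, comparator=comp_out)


# -- microsimulation --------------------------------------------------------


@dataclass
class MicrosimResult:
    """Mean outcomes of simulated individual trajectories."""

    n_patients: int
    yfeod: float
    yfeod_disc: float
    qalys: float
    qalys_disc: float
    life_years: float
    cost: float
    cost_disc: float
    drug_cost: float
    per_patient: Dict[str, np.ndarray] = field(default_factory=dict)

    def se(self, key: str) -> float:
        arr = self.per_patient[key]
        return float(arr.std(ddof=1) / np.sqrt(arr.size))


def _simulate_paths(
    matrices: np.ndarray, uniforms: np.ndarray
) -> np.ndarray:
    """Vectorised path sampling: states[(n, horizon+1)] from per-cycle
    cumulative matrices and pre-drawn uniforms (n, horizon)."""
    n, horizon = uniforms.shape
    states = np.empty((n, horizon + 1), dtype=np.int64)
    states[:, 0] = STATE_INDEX[State.ASYMPTOMATIC]
    cum = matrices.cumsum(axis=2)
    for t in range(horizon):
        rows = cum[t][states[:, t]]
        states[:, t + 1] = (uniforms[:, [t]] > rows).sum(axis=1)
    return states


def microsimulate_outcomes(
    params: ParameterSet,
    strategy: Strategy,
    sexes: np.ndarray,
    uniforms: np.ndarray,
    utility_offset: float = 0.0,
    comparator_first_rrr: bool = False,
) -> MicrosimResult:
    """Simulate individual trajectories given pre-drawn randomness.

    ``sexes`` is an array of "male"/"female" labels and ``uniforms`` a
    ``(n, horizon)`` matrix; sharing both across strategies yields
    common-random-number comparisons.
    """
    horizon = params.horizon
    n = len(sexes)
    u_vec = _utility_vector(params, utility_offset)
    c_vec = _cost_vector(params)
    treated = np.array(
        [[strategy.treats(s, t) for s in STATES] for t in range(horizon)]
    )
    eff_disc = np.array(
        [discount_factor(params.discount_rate_effects, t) for t in range(horizon)]
    )
    cost_disc = np.array(
        [discount_factor(params.discount_rate_costs, t) for t in range(horizon)]
    )
    per_patient = {
        k: np.zeros(n)
        for k in ("yfeod", "yfeod_disc", "qalys", "qalys_disc", "life_years",
                  "cost", "cost_disc", "drug_cost")
    }
    for sex in SEXES:
        mask = sexes == sex
        if not mask.any():
            continue
        mats = np.empty((horizon, N_STATES, N_STATES))
        for t in range(horizon):
            mats[t] = params.transition_matrix(
                sex,
                lambda s, _t=t: strategy.treats(s, _t),
                t,
                comparator_first_rrr=comparator_first_rrr,
            )
        paths = _simulate_paths(mats, uniforms[mask])
        post = paths[:, 1:]  # (m, horizon) post-transition states
        alive = post != _DEATH_IDX
        in_yfeod = np.isin(post, _YFEOD_IDX)
        drug_on = treated[np.arange(horizon)[None, :], post]
        cl = params.cycle_length
        per_patient["life_years"][mask] = alive.sum(axis=1) * cl
        per_patient["yfeod"][mask] = in_yfeod.sum(axis=1) * cl
        per_patient["yfeod_disc"][mask] = (in_yfeod * eff_disc).sum(axis=1) * cl
        util = u_vec[post]
        per_patient["qalys"][mask] = util.sum(axis=1) * cl
        per_patient["qalys_disc"][mask] = (util * eff_disc).sum(axis=1) * cl
        state_cost = c_vec[post]
        drug_cost = drug_on * params.cost_ert
        total = state_cost + drug_cost
        per_patient["cost"][mask] = total.sum(axis=1) * cl
        per_patient["cost_disc"][mask] = (total * cost_disc).sum(axis=1) * cl
        per_patient["drug_cost"][mask] = drug_cost.sum(axis=1) * cl
    return MicrosimResult(
        n_patients=n,
        yfeod=float(per_patient["yfeod"].mean()),
        yfeod_disc=float(per_patient["yfeod_disc"].mean()),
        qalys=float(per_patient["qalys"].mean()),
        qalys_disc=float(per_patient["qalys_disc"].mean()),
        life_years=float(per_patient["life_years"].mean()),
        cost=float(per_patient["cost"].mean()),
        cost_disc=float(per_patient["cost_disc"].mean()),
        drug_cost=float(per_patient["drug_cost"].mean()),
        per_patient=per_patient,
    )


def run_microsim(
    params: ParameterSet,
    strategy: Strategy,
    n_patients: int,
    seed: int | np.random.Generator = 0,
    sex_mix: Optional[float] = None,
) -> MicrosimResult:
    """First-order (patient-level) simulation of ``n_patients`` trajectories.

    Each patient draws a sex from the cohort mix and then a state path by
    categorical sampling from the per-cycle transition matrices.  Fully
    reproducible under a fixed seed.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mix = params.sex_mix if sex_mix is None else sex_mix
    sexes = np.where(rng.random(n_patients) < mix, "male", "female")
    uniforms = rng.random((n_patients, params.horizon))
    return microsimulate_outcomes(params, strategy, sexes, uniforms)
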