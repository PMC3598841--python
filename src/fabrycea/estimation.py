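"""Parameter estimation from patient-level data.

This module turns (synthetic) patient-level observations into the model's
inputs:

* Kaplan-Meier median times-to-event per transition, converted to annual
  probabilities under a constant hazard consistent with the 1-year cycle;
* EQ-5D profiles valued with a time-trade-off tariff and averaged per patient
  per disease-state cluster, then across patients;
* quarterly resource-use questionnaires costed with Dutch unit costs and
  annualised (quarter x 4);
* sick-leave questionnaires converted to annual production-loss costs;
* percentile-bootstrap confidence intervals over patients, with
  method-of-moments beta shape parameters for probabilistic sensitivity
  analysis.

Patient-level files are plain delimited text; see the ``read_*`` helpers for
the exact column schemas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .parameters import (
    ProbabilityEstimate,
    beta_shapes_from_mean_sd,
)
from .states import CLUSTER_OF, GRAPH, STATE_INDEX, Cluster, State, TRANSPLANT_EDGE

__all__ = [
    "Tariff",
    "km_median",
    "annual_probability_from_median",
    "median_from_annual_probability",
    "eq5d_utility",
    "mean_utility_by_cluster",
    "mean_annual_cost_by_cluster",
    "annual_production_loss",
    "bootstrap_beta_ci",
    "estimate_transition_probabilities",
    "DEFAULT_UNIT_COSTS",
    "read_histories",
    "read_eq5d",
    "read_resource_use",
]

EQ5D_DIMENSIONS: Tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")

#: Dutch 2009 unit costs (EUR) for the questionnaire resource categories.
DEFAULT_UNIT_COSTS: Dict[str, float] = {
    "inpatient_days": 457.0,
    "icu_days": 2183.0,
    "daycare_treatments": 251.0,
    "outpatient_visits": 72.0,
    "gp_visits": 28.0,
    "physiotherapist_visits": 36.0,
    "psychologist_visits": 91.5,
    "occupational_physician_visits": 26.0,
    "social_worker_visits": 65.0,
    "alternative_healer_visits": 60.0,
}


# ---------------------------------------------------------------------------
# Kaplan-Meier medians and probability conversion


@dataclass(frozen=True)
class KMMedian:
    """A Kaplan-Meier median; ``unreached`` marks survival never dropping
    to 0.5, in which case ``years`` is the time of the last observed event."""

    years: float
    unreached: bool = False


def km_median(times: Sequence[float], events: Sequence[int]) -> KMMedian:
    """Product-limit median time-to-event.

    The median is the first time at which the Kaplan-Meier survival estimate
    is <= 0.5.  If survival never reaches 0.5 the time of the last observed
    event is returned, flagged ``unreached``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0 or not np.any(events == 1):
        raise ValueError("median undefined: no events observed")
    if np.any(times <= 0):
        raise ValueError("event/censoring times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    # tolerance guards exact-tie medians (S = 1/2) against float round-off
    hit = sf[sf.values <= 0.5 + 1e-12]
    if len(hit):
        return KMMedian(years=float(hit.index[0]), unreached=False)
    last_event = float(times[events == 1].max())
    return KMMedian(years=last_event, unreached=True)


def annual_probability_from_median(median: float, cycle_length: float = 1.0) -> float:
    """Annual transition probability from a median time-to-event.

    Under a constant hazard, a median of ``m`` years implies a per-cycle
    probability ``1 - 2**(-cycle_length/m)``; a 1-year median gives exactly
    0.5 and the probability decreases monotonically in the median.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if cycle_length <= 0:
        raise ValueError("cycle length must be positive")
    return 1.0 - 2.0 ** (-cycle_length / median)


def median_from_annual_probability(p: float, cycle_length: float = 1.0) -> float:
    """Inverse of :func:`annual_probability_from_median` (for generators)."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must lie in (0, 1)")
    return cycle_length * math.log(2.0) / -math.log1p(-p)


# ---------------------------------------------------------------------------
# EQ-5D tariffs and utilities


class Tariff:
    """A named EQ-5D-3L valuation tariff (time-trade-off based).

    The coefficient table maps an EQ-5D profile (five dimensions, levels
    1-3) to a utility: ``1 - constant(any problem) - per-dimension level
    decrements - N3(any level 3)``.  The full-health profile (1,1,1,1,1)
    maps to exactly 1.0; the loader enforces this anchor.
    """

    REQUIRED_TERMS = ("constant",) + tuple(
        f"{dim}{lvl}" for dim in EQ5D_DIMENSIONS for lvl in (2, 3)
    )

    def __init__(self, name: str, coefficients: Mapping[str, float]) -> None:
        missing = [t for t in self.REQUIRED_TERMS if t not in coefficients]
        if missing:
            raise ValueError(f"tariff {name!r} missing terms {missing}")
        self.name = name
        self.coefficients = dict(coefficients)
        self.coefficients.setdefault("N3", 0.0)
        if self.evaluate((1, 1, 1, 1, 1)) != 1.0:
            raise ValueError(f"tariff {name!r} does not anchor full health at 1.0")

    @classmethod
    def from_csv(cls, path: str | Path, name: Optional[str] = None) -> "Tariff":
        frame = pd.read_csv(path)
        if not {"term", "value"}.issubset(frame.columns):
            raise ValueError("tariff file must have columns term,value")
        coeff = dict(zip(frame["term"].astype(str), frame["value"].astype(float)))
        return cls(name or Path(path).stem, coeff)

    @classmethod
    def bundled(cls, which: str = "uk") -> "Tariff":
        """Load a shipped tariff: ``uk`` (MVH TTO) or ``nl`` (Dutch TTO)."""
        fname = {"uk": "tariff_uk_tto.csv", "nl": "tariff_nl_tto.csv"}[which]
        ref = resources.files("fabrycea.data") / fname
        with resources.as_file(ref) as path:
            return cls.from_csv(path, name=which)

    def evaluate(self, profile: Sequence[int]) -> float:
        if len(profile) != 5:
            raise ValueError("EQ-5D profile must have exactly five levels")
        levels = [int(x) for x in profile]
        if any(l not in (1, 2, 3) for l in levels):
            raise ValueError(f"EQ-5D levels must be in {{1,2,3}}, got {levels}")
        if all(l == 1 for l in levels):
            return 1.0
        u = 1.0 - self.coefficients["constant"]
        for dim, level in zip(EQ5D_DIMENSIONS, levels):
            if level > 1:
                u -= self.coefficients[f"{dim}{level}"]
        if any(l == 3 for l in levels):
            u -= self.coefficients["N3"]
        return u

    def utility_table(self) -> pd.DataFrame:
        """Utilities of all 243 profiles (used by the synthetic generator)."""
        rows = []
        for mo in (1, 2, 3):
            for sc in (1, 2, 3):
                for ua in (1, 2, 3):
                    for pd_ in (1, 2, 3):
                        for ad in (1, 2, 3):
                            prof = (mo, sc, ua, pd_, ad)
                            rows.append((*prof, self.evaluate(prof)))
        return pd.DataFrame(
            rows, columns=[*EQ5D_DIMENSIONS, "utility"]
        ).sort_values("utility", ignore_index=True)


def eq5d_utility(profile: Sequence[int], tariff: Tariff) -> float:
    """Value one EQ-5D profile under ``tariff``."""
    return tariff.evaluate(profile)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    lcl: float
    ucl: float
    alpha: float
    beta: float
    degenerate: bool
    n: int

    def as_probability_estimate(self) -> ProbabilityEstimate:
        return ProbabilityEstimate(
            p=self.mean,
            lcl=self.lcl,
            ucl=self.ucl,
            alpha=None if self.degenerate else self.alpha,
            beta=None if self.degenerate else self.beta,
        )


def bootstrap_beta_ci(
    observations: Sequence[float],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BootstrapResult:
    """Percentile bootstrap (2.5/97.5) of a mean on [0, 1] observations,
    with method-of-moments beta shape parameters from the bootstrap
    mean/variance.  Zero-variance samples yield a degenerate point mass."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("no observations")
    if np.any((obs < 0) | (obs > 1)):
        raise ValueError("observations must lie in [0, 1]")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = float(obs.mean())
    if obs.size == 1 or float(obs.std()) == 0.0:
        return BootstrapResult(mean, mean, mean, math.nan, math.nan, True, obs.size)
    idx = rng.integers(0, obs.size, size=(n_boot, obs.size))
    boot_means = obs[idx].mean(axis=1)
    lcl, ucl = np.percentile(boot_means, [2.5, 97.5])
    a, b = beta_shapes_from_mean_sd(float(boot_means.mean()), float(boot_means.std()))
    degenerate = math.isnan(a)
    return BootstrapResult(mean, float(lcl), float(ucl), a, b, degenerate, obs.size)


# ---------------------------------------------------------------------------
# Delimited-file readers


def read_histories(path: str | Path) -> pd.DataFrame:
    """Read event histories: ``patient_id,sex,state,entry_age,exit_age,next_state``
    with an empty ``next_state`` meaning censored in that state."""
    frame = pd.read_csv(path, dtype={"patient_id": str, "next_state": str})
    required = {"patient_id", "sex", "state", "entry_age", "exit_age", "next_state"}
    if not required.issubset(frame.columns):
        raise ValueError(f"histories file must have columns {sorted(required)}")
    frame["next_state"] = frame["next_state"].replace({np.nan: ""})
    validate_histories(frame)
    return frame


def validate_histories(frame: pd.DataFrame) -> None:
    if (frame["entry_age"] >= frame["exit_age"]).any():
        raise ValueError("entry_age must be strictly below exit_age")
    for row in frame.itertuples():
        s = State(row.state)
        if row.next_state:
            t = State(row.next_state)
            if (s, t) not in GRAPH:
                raise ValueError(f"history transition {s.value}->{t.value} not allowed")
    # consecutive records of one patient must chain
    for _, grp in frame.groupby("patient_id"):
        grp = grp.sort_values("entry_age")
        nxt = grp["next_state"].to_numpy()
        states = grp["state"].to_numpy()
        for a, b in zip(nxt[:-1], states[1:]):
            if a != b:
                raise ValueError("history records of a patient do not chain")


def read_eq5d(path: str | Path) -> pd.DataFrame:
    """Read EQ-5D records: ``patient_id,quarter,state,MO,SC,UA,PD,AD``."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "quarter", "state", *EQ5D_DIMENSIONS}
    if not required.issubset(frame.columns):
        raise ValueError(f"EQ-5D file must have columns {sorted(required)}")
    for dim in EQ5D_DIMENSIONS:
        if not frame[dim].isin([1, 2, 3]).all():
            raise ValueError(f"EQ-5D dimension {dim} has levels outside {{1,2,3}}")
    return frame


def read_resource_use(path: str | Path) -> pd.DataFrame:
    """Read resource-use records; one column per resource category plus the
    work-pattern fields used for production loss."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "quarter", "state"}
    if not required.issubset(frame.columns):
        raise ValueError(f"resource file must have columns {sorted(required)}")
    return frame


# ---------------------------------------------------------------------------
# Cluster-level summaries


def _cluster_of_states(states: pd.Series) -> pd.Series:
    return states.map(lambda s: CLUSTER_OF[State(s)].value)


def mean_utility_by_cluster(
    records: pd.DataFrame,
    tariff: Tariff,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean health utility per disease-state cluster with bootstrap 95% CI.

    Two-stage averaging: utilities are averaged per patient within a cluster
    first, then across patients, so patients with many questionnaires do not
    dominate.  The bootstrap resamples patients (repeated measures within a
    patient are not independent).  Clusters without observations are
    reported with a missing (NaN) utility, never zero.
    """
    recs = records.copy()
    recs["utility"] = [
        tariff.evaluate(row) for row in recs[list(EQ5D_DIMENSIONS)].to_numpy()
    ]
    recs["cluster"] = _cluster_of_states(recs["state"])
    per_patient = (
        recs.groupby(["cluster", "patient_id"])["utility"].mean().reset_index()
    )
    rng = np.random.default_rng(seed)
    rows = []
    for cluster in (c for c in Cluster if c is not Cluster.DEAD):
        sub = per_patient[per_patient["cluster"] == cluster.value]
        if sub.empty:
            rows.append((cluster.value, 0, math.nan, math.nan, math.nan, True))
            continue
        values = np.clip(sub["utility"].to_numpy(), 0.0, 1.0)
        boot = bootstrap_beta_ci(values, n_boot=n_boot, seed=rng)
        rows.append(
            (cluster.value, len(sub), boot.mean, boot.lcl, boot.ucl, False)
        )
    return pd.DataFrame(
        rows, columns=["cluster", "n", "mean", "lcl", "ucl", "missing"]
    )


def mean_annual_cost_by_cluster(
    records: pd.DataFrame,
    unit_costs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Mean annual health-care cost (EUR) per disease-state cluster.

    Quarterly resource counts are costed with the unit-cost table,
    multiplied by four to get annual figures, averaged per patient per
    cluster and then across patients.
    """
    unit_costs = DEFAULT_UNIT_COSTS if unit_costs is None else dict(unit_costs)
    meta_cols = {
        "patient_id", "quarter", "state",
        "sick_leave_days_fortnight", "hours_per_day", "days_per_week",
        "employment_status",
    }
    categories = [c for c in records.columns if c not in meta_cols]
    unknown = [c for c in categories if c not in unit_costs]
    if unknown:
        raise ValueError(f"unknown resource categories: {unknown}")
    recs = records.copy()
    if (recs[categories] < 0).any().any():
        raise ValueError("resource counts must be non-negative")
    quarterly = sum(
        recs[cat].to_numpy(dtype=float) * unit_costs[cat] for cat in categories
    )
    recs["annual_cost"] = np.asarray(quarterly, dtype=float) * 4.0
    recs["cluster"] = _cluster_of_states(recs["state"])
    per_patient = (
        recs.groupby(["cluster", "patient_id"])["annual_cost"].mean().reset_index()
    )
    out = (
        per_patient.groupby("cluster")["annual_cost"]
        .agg(["count", "mean"])
        .rename(columns={"count": "n", "mean": "mean_annual_cost"})
        .reset_index()
    )
    return out


def annual_production_loss(
    records: pd.DataFrame,
    unit_cost_hour: float = 30.0,
) -> pd.DataFrame:
    """Mean annual production-loss cost (EUR) per cluster from sick-leave data.

    For patients with paid work, the individual mean sick-leave volume
    (days per fortnight) is multiplied by 26 and by the overall mean number
    of working hours per working day among employed patients, then by the
    hourly cost.  Permanently sick-listed patients (because of the disease)
    count a full-time-equivalent year at the overall mean working pattern.
    Patients without paid work for unrelated reasons contribute zero.
    """
    required = {
        "sick_leave_days_fortnight", "hours_per_day", "days_per_week",
        "employment_status",
    }
    if not required.issubset(records.columns):
        raise ValueError(f"resource file missing work-pattern columns {sorted(required)}")
    if (records["sick_leave_days_fortnight"] < 0).any():
        raise ValueError("negative sick leave")
    recs = records.copy()
    employed = recs[recs["employment_status"] == "employed"]
    mean_hours = float(employed["hours_per_day"].mean()) if len(employed) else 0.0
    mean_days_week = float(employed["days_per_week"].mean()) if len(employed) else 0.0

    def annual_cost(row) -> float:
        status = row.employment_status
        if status == "employed":
            return row.sick_leave_days_fortnight * 26.0 * mean_hours * unit_cost_hour
        if status == "permanent_sick_leave":
            return 52.0 * mean_days_week * mean_hours * unit_cost_hour
        if status == "not_employed_other":
            return 0.0
        raise ValueError(f"unknown employment status {status!r}")

    recs["annual_loss"] = [annual_cost(row) for row in recs.itertuples()]
    recs["cluster"] = _cluster_of_states(recs["state"])
    per_patient = (
        recs.groupby(["cluster", "patient_id"])["annual_loss"].mean().reset_index()
    )
    return (
        per_patient.groupby("cluster")["annual_loss"]
        .agg(["count", "mean"])
        .rename(columns={"count": "n", "mean": "mean_annual_loss"})
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Transition probabilities from event histories


def estimate_transition_probabilities(
    histories: pd.DataFrame,
    per_sex: bool = True,
    cycle_length: float = 1.0,
    n_boot: int = 500,
    seed: int = 0,
) -> Dict[Tuple[State, State], Dict[str, ProbabilityEstimate]]:
    """Kaplan-Meier medians per transition, converted to annual probabilities.

    For each permitted edge, the sojourn time in the source state is the
    time-to-event for records that exit along that edge; records leaving
    along a competing edge, dying, or censored count as censored.  When the
    product-limit survival never reaches 0.5 within follow-up (rare
    transitions), the annual probability falls back to the constant-hazard
    person-time estimator ``1 - exp(-events / person-years)``; the
    ``median_unreached`` flag records which estimates used the fallback.
    The bootstrap (over patients) yields 95% confidence limits on the
    annual probability and method-of-moments beta shapes.

    Set ``per_sex=False`` to pool both sexes (sparse transitions); the mode
    is recorded in the returned estimates via run metadata upstream.
    """
    rng = np.random.default_rng(seed)
    out: Dict[Tuple[State, State], Dict[str, ProbabilityEstimate]] = {}
    frame = histories.copy()
    frame["duration"] = frame["exit_age"] - frame["entry_age"]
    edges = GRAPH.progression_edges() + [TRANSPLANT_EDGE]

    def annual_p(times: np.ndarray, events: np.ndarray) -> Tuple[float, bool]:
        med = km_median(times, events)
        if med.unreached:
            rate = events.sum() / times.sum()
            return 1.0 - math.exp(-rate), True
        return annual_probability_from_median(med.years, cycle_length), False
    for edge in edges:
        src, dst = edge
        sub_all = frame[frame["state"] == src.value]
        by_sex: Dict[str, ProbabilityEstimate] = {}
        sex_groups = ("male", "female") if per_sex else ("pooled",)
        for sex in sex_groups:
            sub = sub_all if sex == "pooled" else sub_all[sub_all["sex"] == sex]
            if sub.empty:
                continue
            times = sub["duration"].to_numpy(dtype=float)
            events = (sub["next_state"] == dst.value).to_numpy(dtype=int)
            if events.sum() == 0:
                continue
            p, unreached = annual_p(times, events)
            # bootstrap over patients (repeated measures within patient)
            pt_times = []
            pt_events = []
            for _, g in sub.groupby("patient_id"):
                pt_times.append(g["duration"].to_numpy(dtype=float))
                pt_events.append(
                    (g["next_state"] == dst.value).to_numpy(dtype=np.int64)
                )
            n_pat = len(pt_times)
            boot_ps = []
            for _ in range(n_boot):
                pick = rng.integers(0, n_pat, size=n_pat)
                bt = np.concatenate([pt_times[i] for i in pick])
                be = np.concatenate([pt_events[i] for i in pick])
                if be.sum() == 0:
                    continue
                try:
                    bp, _ = annual_p(bt, be)
                except ValueError:
                    continue
                boot_ps.append(bp)
            if boot_ps:
                lcl, ucl = np.percentile(boot_ps, [2.5, 97.5])
                a, b = beta_shapes_from_mean_sd(
                    float(np.mean(boot_ps)), float(np.std(boot_ps))
                )
            else:
                lcl = ucl = p
                a = b = math.nan
            est = ProbabilityEstimate(
                p=p,
                lcl=float(lcl),
                ucl=float(ucl),
                alpha=None if math.isnan(a) else a,
                beta=None if math.isnan(b) else b,
                median_unreached=unreached,
            )
            by_sex[sex] = est
        if by_sex:
            if not per_sex:
                only = by_sex["pooled"]
                by_sex = {"male": only, "female": only}
            out[edge] = by_sex
    return out
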