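"""Cost-effectiveness statistics: ICERs, net monetary benefit, two-stage
probabilistic sensitivity analysis and the acceptability curve.

The PSA follows a two-stage Monte-Carlo design: the outer stage draws each
annual transition probability from its beta distribution (second-order,
parameter uncertainty); the inner stage runs a small number of
microsimulated patients per strategy (first-order, patient heterogeneity),
by default with common random numbers across the two arms.  The net
monetary benefit ``NMB = wtp * dQALYs - dcost`` is evaluated per draw on a
willingness-to-pay grid and the cost-effectiveness acceptability curve
(CEAC) reports the fraction of draws with positive NMB at each
willingness-to-pay value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Strategy, microsimulate_outcomes
from .parameters import ParameterSet

__all__ = [
    "ICER",
    "icer",
    "nmb",
    "required_qalys_per_year",
    "PSAResult",
    "run_psa",
    "ceac",
]


@dataclass(frozen=True)
class ICER:
    """An incremental cost-effectiveness ratio with its dominance label.

    ``label`` is ``"icer"`` for a regular ratio, ``"dominant"`` when the
    active strategy is cheaper and more effective, ``"dominated"`` when it
    is dearer and less effective, and ``"undefined, dominance check"`` for a
    zero effect difference (the ratio is then NaN)."""

    value: float
    label: str
    delta_cost: float
    delta_effect: float

    def __float__(self) -> float:
        return self.value


def icer(delta_cost: float, delta_effect: float) -> ICER:
    """Incremental cost per unit of incremental effect."""
    if delta_effect == 0.0:
        return ICER(math.nan, "undefined, dominance check", delta_cost, delta_effect)
    value = delta_cost / delta_effect
    if delta_cost > 0 and delta_effect < 0:
        label = "dominated"
    elif delta_cost < 0 and delta_effect > 0:
        label = "dominant"
    else:
        label = "icer"
    return ICER(value, label, delta_cost, delta_effect)


def nmb(wtp: float, delta_qalys: float, delta_cost: float) -> float:
    """Net monetary benefit at a willingness-to-pay per QALY."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * delta_qalys - delta_cost


def required_qalys_per_year(delta_cost: float, wtp: float, window: float) -> float:
    """QALYs a treatment must generate per year to break even.

    Spreads the incremental lifetime cost over a treatment window and asks
    how many QALYs per year would be needed at the given willingness-to-pay:
    ``delta_cost / (wtp * window)``.
    """
    if wtp <= 0 or window <= 0:
        raise ValueError("wtp and window must be positive")
    return delta_cost / (wtp * window)


@dataclass
class PSAResult:
    """Per-draw incremental outcomes and the derived NMB surface.

    ``delta_*`` arrays are undiscounted (the acceptability curve is reported
    without discounting); discounted variants are kept alongside.  ``nmb``
    has shape ``(n_draws, n_wtp)`` and satisfies
    ``nmb[i, j] = wtp[j] * delta_qalys[i] - delta_cost[i]`` exactly.
    """

    wtp_grid: np.ndarray
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    delta_yfeod: np.ndarray
    delta_cost_disc: np.ndarray
    delta_qalys_disc: np.ndarray
    delta_yfeod_disc: np.ndarray
    seed: Optional[int] = None
    settings: Dict[str, object] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.delta_cost.size

    @property
    def nmb(self) -> np.ndarray:
        return np.outer(self.delta_qalys, self.wtp_grid) - self.delta_cost[:, None]

    def ceac(self) -> np.ndarray:
        return (self.nmb > 0).mean(axis=0)

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac()})

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
                "delta_yfeod": self.delta_yfeod,
                "delta_cost_disc": self.delta_cost_disc,
                "delta_qalys_disc": self.delta_qalys_disc,
                "delta_yfeod_disc": self.delta_yfeod_disc,
            }
        )


def ceac(psa: PSAResult) -> np.ndarray:
    """Probability of positive net monetary benefit at each WTP value."""
    return psa.ceac()


def run_psa(
    params: ParameterSet,
    n_outer: int = 1000,
    n_inner: int = 10,
    wtp_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    active: Optional[Strategy] = None,
    comparator: Optional[Strategy] = None,
    common_random_numbers: bool = True,
    first_order: bool = True,
) -> PSAResult:
    """Two-stage Monte-Carlo probabilistic sensitivity analysis.

    Outer loop: draw a complete transition-probability set from the beta
    distributions (utilities and costs stay fixed).  Inner loop: simulate
    ``n_inner`` patients per strategy and average the incremental outcomes
    within the draw.  With ``common_random_numbers`` the two arms share the
    patient-level random streams (variance reduction); the alternative mode
    draws fresh streams per arm.  ``first_order=False`` replaces the inner
    microsimulation by the deterministic cohort expectation (no first-order
    noise; degenerate beta parameters then collapse the whole PSA onto the
    base case).  Reproducible bit-for-bit under a fixed seed.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be positive")
    active = active or Strategy.from_rule(params.ert_start_rule)
    comparator = comparator or Strategy.no_ert()
    grid = np.asarray(
        params.wtp_grid if wtp_grid is None else list(wtp_grid), dtype=float
    )
    if grid.size == 0:
        grid = np.logspace(math.log10(20_000), math.log10(10_000_000), 25)
    rng = np.random.default_rng(seed)

    d_cost = np.empty(n_outer)
    d_qaly = np.empty(n_outer)
    d_yfeod = np.empty(n_outer)
    d_cost_d = np.empty(n_outer)
    d_qaly_d = np.empty(n_outer)
    d_yfeod_d = np.empty(n_outer)
    for i in range(n_outer):
        draw = params.sample_transition_probabilities(rng)
        if not first_order:
            from .engine import evaluate_strategy

            res_a = evaluate_strategy(draw, active)["all"]
            res_c = evaluate_strategy(draw, comparator)["all"]
        else:
            sexes = np.where(rng.random(n_inner) < params.sex_mix, "male", "female")
            uniforms = rng.random((n_inner, params.horizon))
            res_a = microsimulate_outcomes(draw, active, sexes, uniforms)
            if common_random_numbers:
                res_c = microsimulate_outcomes(draw, comparator, sexes, uniforms)
            else:
                sexes_c = np.where(rng.random(n_inner) < params.sex_mix, "male", "female")
                uniforms_c = rng.random((n_inner, params.horizon))
                res_c = microsimulate_outcomes(draw, comparator, sexes_c, uniforms_c)
        d_cost[i] = res_a.cost - res_c.cost
        d_qaly[i] = res_a.qalys - res_c.qalys
        d_yfeod[i] = res_a.yfeod - res_c.yfeod
        d_cost_d[i] = res_a.cost_disc - res_c.cost_disc
        d_qaly_d[i] = res_a.qalys_disc - res_c.qalys_disc
        d_yfeod_d[i] = res_a.yfeod_disc - res_c.yfeod_disc

    return PSAResult(
        wtp_grid=grid,
        delta_cost=d_cost,
        delta_qalys=d_qaly,
        delta_yfeod=d_yfeod,
        delta_cost_disc=d_cost_d,
        delta_qalys_disc=d_qaly_d,
        delta_yfeod_disc=d_yfeod_d,
        seed=seed,
        settings={
            "n_outer": n_outer,
            "n_inner": n_inner,
            "active": active.name,
            "comparator": comparator.name,
            "common_random_numbers": common_random_numbers,
            "first_order": first_order,
        },
    )
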