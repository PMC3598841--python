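"""Treatment-effect transform: per-treatment-year odds ratios to per-cycle
relative risk reductions.

The effect of enzyme replacement therapy was estimated as an odds ratio *per
year of treatment* for progressing to the next complication (0.82 for a first
complication, 0.52 for a second).  The model needs a per-cycle (annual)
relative risk reduction (RRR).  The conversion runs in three steps:

1. cumulate the untreated annual probability over the median treatment
   duration ``d`` in the state: ``P0 = 1 - (1 - p)**d``;
2. compound the odds ratio over the same window, ``odds1 = odds0 * or**d``,
   giving the treated cumulative risk ``P1`` and the cumulative RRR
   ``1 - P1/P0``;
3. de-cumulate ``P1`` back to an annual probability under a constant hazard,
   ``p1 = 1 - (1 - P1)**(1/d)``, giving the per-cycle RRR ``1 - p1/p``.

The treated transition probability is then simply ``p * (1 - rrr_per_cycle)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


def cumulative_risk(p_annual: float, years: float) -> float:
    """Risk of at least one event over ``years`` at constant annual risk ``p``."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    if years <= 0:
        raise ValueError("duration must be positive")
    return 1.0 - (1.0 - p_annual) ** years


def rrr_over_duration(p_annual_untreated: float, or_per_year: float, duration: float) -> float:
    """Cumulative relative risk reduction over the median treatment duration.

    The odds ratio per treatment-year compounds multiplicatively over the
    window: ``odds(d) = odds(0) * or**d``.
    """
    if or_per_year <= 0:
        raise ValueError("odds ratio must be positive")
    p0 = cumulative_risk(p_annual_untreated, duration)
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError(
            f"cumulative untreated risk {p0} leaves treated odds undefined"
        )
    odds0 = p0 / (1.0 - p0)
    odds1 = odds0 * or_per_year**duration
    p1 = odds1 / (1.0 + odds1)
    return 1.0 - p1 / p0


def per_cycle_rrr(p_annual_untreated: float, rrr_cumulative: float, duration: float) -> float:
    """Annualised relative risk reduction implied by a cumulative RRR."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if p_annual_untreated <= 0.0 or p_annual_untreated >= 1.0:
        raise ValueError("untreated annual probability must lie in (0, 1)")
    p0 = cumulative_risk(p_annual_untreated, duration)
    p1_cum = p0 * (1.0 - rrr_cumulative)
    p1 = 1.0 - (1.0 - p1_cum) ** (1.0 / duration)
    return 1.0 - p1 / p_annual_untreated


def per_cycle_rrr_from_or(
    p_annual_untreated: float, or_per_year: float, duration: float
) -> float:
    """Compose :func:`rrr_over_duration` and :func:`per_cycle_rrr`."""
    rrr_cum = rrr_over_duration(p_annual_untreated, or_per_year, duration)
    return per_cycle_rrr(p_annual_untreated, rrr_cum, duration)


def treated_probability(p_untreated: float, rrr_per_cycle: float) -> float:
    """Annual transition probability under treatment: ``p * (1 - rrr)``.

    A harmful effect (``rrr < 0``) can push the product above 1; the result
    is clipped with a warning.
    """
    if not 0.0 <= p_untreated <= 1.0:
        raise ValueError(f"probability {p_untreated} outside [0, 1]")
    p = p_untreated * (1.0 - rrr_per_cycle)
    if p > 1.0:
        warnings.warn("treated probability clipped to 1", stacklevel=2)
        return 1.0
    if p < 0.0:
        return 0.0
    return p


@dataclass(frozen=True)
class TreatmentEffect:
    """A per-treatment-year odds ratio with its annualisation context."""

    or_per_year: float
    median_duration: float

    def __post_init__(self) -> None:
        if self.or_per_year <= 0:
            raise ValueError("odds ratio must be positive")
        if self.median_duration <= 0:
            raise ValueError("median duration must be positive")

    def rrr_cumulative(self, p_annual_untreated: float) -> float:
        if self.or_per_year == 1.0:
            return 0.0
        return rrr_over_duration(p_annual_untreated, self.or_per_year, self.median_duration)

    def rrr_per_cycle(self, p_annual_untreated: float) -> float:
        if self.or_per_year == 1.0 or p_annual_untreated == 0.0:
            return 0.0
        return per_cycle_rrr_from_or(
            p_annual_untreated, self.or_per_year, self.median_duration
        )

    def treated_probability(self, p_annual_untreated: float) -> float:
        return treated_probability(
            p_annual_untreated, self.rrr_per_cycle(p_annual_untreated)
        )
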