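"""Estimation stage: KM medians, tariffs, cluster summaries, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from fabrycea import (
    Tariff,
    annual_probability_from_median,
    annual_production_loss,
    bootstrap_beta_ci,
    eq5d_utility,
    km_median,
    mean_annual_cost_by_cluster,
    mean_utility_by_cluster,
)
from fabrycea.estimation import EQ5D_DIMENSIONS, median_from_annual_probability


def product_limit_median(times, events):
    """Independent brute-force product-limit table (oracle for km_median).

    Exact rational arithmetic, so ties where survival equals exactly 1/2
    are resolved without float round-off."""
    from fractions import Fraction

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times)
    times, events = times[order], events[order]
    surv = Fraction(1)
    at_risk = len(times)
    for t in np.unique(times):
        d = int(((times == t) & (events == 1)).sum())
        c = int(((times == t) & (events == 0)).sum())
        if d > 0:
            surv *= Fraction(at_risk - d, at_risk)
        at_risk -= d + c
        if surv <= Fraction(1, 2):
            return float(t)
    return None  # median unreached


class TestKMMedian:
    def test_degenerate_all_events_same_time(self):
        med = km_median([2, 2, 2, 2, 2], [1, 1, 1, 1, 1])
        assert med.years == 2.0 and not med.unreached

    def test_hand_computed_product_limit_table(self):
        # survival steps: 0.8, 0.6, (censor), then 0.6 * 1/2 = 0.3 at t=4
        med = km_median([1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
        assert med.years == 4.0 and not med.unreached

    def test_agrees_with_brute_force_oracle_on_small_fixtures(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 11))
            times = np.round(rng.uniform(0.5, 10, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            oracle = product_limit_median(times, events)
            med = km_median(times, events)
            if oracle is None:
                assert med.unreached
            else:
                assert med.years == pytest.approx(oracle)
                assert not med.unreached

    def test_monte_carlo_consistency_exponential(self, rng):
        times = rng.exponential(1.0 / math.log(2), 5000)
        med = km_median(times, np.ones(5000, int))
        assert med.years == pytest.approx(1.0, abs=0.05)

    def test_unreached_median_returns_last_event_flagged(self):
        med = km_median([1, 2, 3, 4], [1, 0, 0, 0])
        assert med.unreached and med.years == 1.0

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="median undefined"):
            km_median([1, 2, 3], [0, 0, 0])


class TestMedianToProbability:
    def test_one_year_median_is_exactly_half(self):
        assert annual_probability_from_median(1.0) == 0.5

    def test_two_year_median_closed_form(self):
        assert annual_probability_from_median(2.0) == pytest.approx(
            1 - 2 ** -0.5, abs=1e-12
        )

    def test_strictly_decreasing_and_vanishing(self):
        meds = np.linspace(0.5, 400, 200)
        ps = [annual_probability_from_median(m) for m in meds]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 0.002

    def test_inverse_round_trip(self):
        for p in (0.01, 0.3, 0.9):
            m = median_from_annual_probability(p)
            assert annual_probability_from_median(m) == pytest.approx(p, abs=1e-12)

    def test_invalid_median_raises(self):
        with pytest.raises(ValueError):
            annual_probability_from_median(0.0)


class TestTariff:
    def test_full_health_anchors_at_one(self):
        for which in ("uk", "nl"):
            assert Tariff.bundled(which).evaluate((1, 1, 1, 1, 1)) == 1.0

    def test_single_level2_decrement_matches_coefficient_sum(self):
        uk = Tariff.bundled("uk")
        expected = 1.0 - uk.coefficients["constant"] - uk.coefficients["AD2"]
        assert eq5d_utility((1, 1, 1, 1, 2), uk) == pytest.approx(expected)
        # independent hand evaluation of the shipped file: 1 - 0.081 - 0.071
        assert eq5d_utility((1, 1, 1, 1, 2), uk) == pytest.approx(0.848)

    def test_any_level3_term_applies_once(self):
        uk = Tariff.bundled("uk")
        u = eq5d_utility((3, 1, 1, 1, 1), uk)
        assert u == pytest.approx(1 - 0.081 - 0.314 - 0.269)

    def test_dutch_at_least_uk_on_fixture_profiles(self):
        """The Dutch tariff penalises the fixture profiles less than the UK
        one (lower losses in health utility during progression)."""
        uk, nl = Tariff.bundled("uk"), Tariff.bundled("nl")
        fixtures = [
            (2, 1, 1, 1, 1),
            (1, 2, 1, 1, 1),
            (2, 2, 2, 2, 1),
            (2, 2, 1, 2, 1),
            (3, 2, 2, 3, 1),
            (3, 3, 3, 3, 3),
        ]
        for prof in fixtures:
            assert nl.evaluate(prof) >= uk.evaluate(prof)

    def test_invalid_levels_raise(self):
        uk = Tariff.bundled("uk")
        with pytest.raises(ValueError):
            uk.evaluate((0, 1, 1, 1, 1))
        with pytest.raises(ValueError):
            uk.evaluate((1, 1, 1, 1))


def _records(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "quarter", "state", *EQ5D_DIMENSIONS]
    )


class TestUtilityByCluster:
    def test_two_stage_averaging_not_pooled(self):
        """Patient A (0.8, 0.9), patient B (0.6): the cluster mean is the
        mean of patient means 0.725, not the pooled 0.766."""

        class FakeTariff:
            def evaluate(self, profile):
                return {(2, 1, 1, 1, 1): 0.8, (1, 2, 1, 1, 1): 0.9,
                        (3, 1, 1, 1, 1): 0.6}[tuple(profile)]

        recs = _records(
            [
                ("A", 0, "symptoms", 2, 1, 1, 1, 1),
                ("A", 1, "symptoms", 1, 2, 1, 1, 1),
                ("B", 0, "symptoms", 3, 1, 1, 1, 1),
            ]
        )
        out = mean_utility_by_cluster(recs, FakeTariff(), n_boot=100)
        row = out[out.cluster == "acro_or_symptoms"].iloc[0]
        assert row["mean"] == pytest.approx(0.725)
        assert row["n"] == 2

    def test_two_stage_equals_pooled_with_one_record_per_patient(self, rng):
        uk = Tariff.bundled("uk")
        rows = []
        profiles = [(1, 1, 1, 1, 1), (2, 1, 1, 1, 1), (1, 1, 2, 1, 1)]
        for i in range(30):
            rows.append((f"p{i}", 0, "cardiac", *profiles[i % 3]))
        out = mean_utility_by_cluster(_records(rows), uk, n_boot=100)
        row = out[out.cluster == "single_complication"].iloc[0]
        pooled = np.mean([uk.evaluate(p) for p in profiles * 10])
        assert row["mean"] == pytest.approx(pooled)

    def test_empty_cluster_flagged_missing_not_zero(self):
        uk = Tariff.bundled("uk")
        recs = _records([("A", 0, "symptoms", 1, 1, 1, 1, 1)])
        out = mean_utility_by_cluster(recs, uk, n_boot=100)
        row = out[out.cluster == "multiple_complications"].iloc[0]
        assert bool(row["missing"]) and math.isnan(row["mean"])


class TestCostByCluster:
    def test_two_gp_visits_cost_224_per_year(self):
        recs = pd.DataFrame(
            [("A", 0, "symptoms", 2)],
            columns=["patient_id", "quarter", "state", "gp_visits"],
        )
        out = mean_annual_cost_by_cluster(recs)
        row = out[out.cluster == "acro_or_symptoms"].iloc[0]
        assert row["mean_annual_cost"] == pytest.approx(2 * 28 * 4)

    def test_zero_utilisation_costs_zero(self):
        recs = pd.DataFrame(
            [("A", 0, "cardiac", 0)],
            columns=["patient_id", "quarter", "state", "inpatient_days"],
        )
        out = mean_annual_cost_by_cluster(recs)
        assert out["mean_annual_cost"].iloc[0] == 0.0

    def test_unknown_category_named_in_error(self):
        recs = pd.DataFrame(
            [("A", 0, "cardiac", 1)],
            columns=["patient_id", "quarter", "state", "leech_therapy"],
        )
        with pytest.raises(ValueError, match="leech_therapy"):
            mean_annual_cost_by_cluster(recs)


class TestProductionLoss:
    COLS = [
        "patient_id", "quarter", "state", "sick_leave_days_fortnight",
        "hours_per_day", "days_per_week", "employment_status",
    ]

    def test_one_day_per_fortnight_at_8h(self):
        recs = pd.DataFrame(
            [("A", 0, "symptoms", 1.0, 8.0, 5.0, "employed")], columns=self.COLS
        )
        out = annual_production_loss(recs)
        assert out["mean_annual_loss"].iloc[0] == pytest.approx(26 * 8 * 30)

    def test_not_employed_other_reason_is_zero(self):
        recs = pd.DataFrame(
            [("A", 0, "symptoms", 0.0, 0.0, 0.0, "not_employed_other"),
             ("B", 0, "symptoms", 2.0, 8.0, 5.0, "employed")],
            columns=self.COLS,
        )
        out = annual_production_loss(recs)
        per = out[out.cluster == "acro_or_symptoms"].iloc[0]
        # patient A contributes 0, B contributes 2*26*8*30
        assert per["mean_annual_loss"] == pytest.approx((0 + 2 * 26 * 8 * 30) / 2)

    def test_permanent_sick_leave_full_time_equivalent(self):
        recs = pd.DataFrame(
            [("A", 0, "cardiac", 0.0, 0.0, 0.0, "permanent_sick_leave"),
             ("B", 0, "cardiac", 0.0, 8.0, 5.0, "employed")],
            columns=self.COLS,
        )
        out = annual_production_loss(recs)
        row = out[out.cluster == "single_complication"].iloc[0]
        # A: FTE year at the employed mean pattern = 52*5*8*30; B: zero leave
        assert row["mean_annual_loss"] == pytest.approx(52 * 5 * 8 * 30 / 2)

    def test_negative_sick_leave_raises(self):
        recs = pd.DataFrame(
            [("A", 0, "symptoms", -1.0, 8.0, 5.0, "employed")], columns=self.COLS
        )
        with pytest.raises(ValueError, match="negative sick leave"):
            annual_production_loss(recs)


class TestBootstrapBetaCI:
    def test_constant_sample_is_degenerate_point_mass(self):
        out = bootstrap_beta_ci([0.5] * 20, n_boot=200, seed=1)
        assert out.mean == out.lcl == out.ucl == 0.5
        assert out.degenerate

    def test_beta_sample_recovery(self, rng):
        obs = rng.beta(2, 8, 500)
        out = bootstrap_beta_ci(obs, n_boot=500, seed=2)
        assert out.mean == pytest.approx(0.2, abs=0.03)
        assert not out.degenerate
        assert out.alpha / (out.alpha + out.beta) == pytest.approx(out.mean, abs=0.01)

    def test_ci_ordering_and_bounds(self, rng):
        for _ in range(20):
            obs = rng.uniform(0, 1, int(rng.integers(3, 50)))
            out = bootstrap_beta_ci(obs, n_boot=200, seed=3)
            assert 0.0 <= out.lcl <= out.mean <= out.ucl <= 1.0

    def test_reproducible_under_seed(self):
        obs = np.linspace(0.1, 0.9, 40)
        a = bootstrap_beta_ci(obs, n_boot=300, seed=7)
        b = bootstrap_beta_ci(obs, n_boot=300, seed=7)
        assert (a.lcl, a.ucl, a.alpha, a.beta) == (b.lcl, b.ucl, b.alpha, b.beta)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_beta_ci([1.5], n_boot=200)
        with pytest.raises(ValueError):
            bootstrap_beta_ci([0.5], n_boot=10)
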