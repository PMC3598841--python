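"""Cohort engine, microsimulation and accruals."""

import numpy as np
import pytest

from fabrycea import (
    Strategy,
    accrue_costs,
    accrue_qalys,
    accrue_yfeod,
    compare_strategies,
    discount_factor,
    evaluate_strategy,
    run_cohort,
    run_microsim,
)
from fabrycea.engine import microsimulate_outcomes
from fabrycea.states import Cluster, State

from conftest import make_toy_params


TREAT_ALL = Strategy("treat_all", lambda s, a: True)


class TestDiscountFactor:
    def test_zero_rate_is_one_everywhere(self):
        assert all(discount_factor(0.0, t) == 1.0 for t in range(100))

    def test_four_percent_second_year(self):
        assert discount_factor(0.04, 1) == pytest.approx(0.96154, abs=1e-5)

    def test_first_model_year_undiscounted(self):
        assert discount_factor(0.04, 0) == 1.0

    def test_strictly_decreasing_for_positive_rate(self):
        f = [discount_factor(0.015, t) for t in range(50)]
        assert all(a > b for a, b in zip(f, f[1:]))

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)
        with pytest.raises(ValueError):
            discount_factor(0.04, -1)


class TestCohortTrace:
    def test_immortal_asymptomatic_cohort(self, toy_immortal):
        trace = run_cohort(toy_immortal, Strategy.no_ert(), "male")
        assert trace.total_yfeod() == pytest.approx(70.0)
        assert trace.total_life_years() == pytest.approx(70.0)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    def test_two_state_geometric_life_expectancy(self):
        """alive -> death with p = 0.1: undiscounted life-years equal the
        geometric series sum_{t=1..70} 0.9^t."""
        params = make_toy_params(death_any=0.1)
        trace = run_cohort(params, Strategy.no_ert(), "female")
        expected = sum(0.9**t for t in range(1, 71))
        assert trace.total_life_years() == pytest.approx(expected, abs=1e-9)

    def test_mass_conservation_and_death_monotone(self, base_params):
        trace = run_cohort(base_params, Strategy.ert_at_symptoms(), "male")
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(trace.occupancy >= -1e-15)
        death = trace.occupancy[:, -1]
        assert np.all(np.diff(death) >= -1e-15)

    def test_yfeod_bounded_by_life_years_bounded_by_horizon(self, base_params):
        for sex in ("male", "female"):
            tr = run_cohort(base_params, Strategy.no_ert(), sex)
            assert tr.total_yfeod() <= tr.total_life_years() + 1e-12
            assert tr.total_life_years() <= 70.0 + 1e-12

    def test_discounted_never_exceeds_undiscounted(self, base_params):
        tr = run_cohort(base_params, Strategy.ert_at_symptoms(), "female")
        assert tr.total_yfeod(True) <= tr.total_yfeod(False)
        assert tr.total_qalys(True) <= tr.total_qalys(False)
        assert tr.total_cost(True) <= tr.total_cost(False)

    def test_trace_export_has_one_row_per_cycle(self, base_params):
        frame = run_cohort(base_params, Strategy.no_ert(), "male").to_frame()
        assert len(frame) == 70
        assert "occ_death" in frame.columns and "qalys" in frame.columns


FULL_UTILITIES = {
    Cluster.ASYMPTOMATIC: 0.874,
    Cluster.ACRO_OR_SYMPTOMS: 0.762,
    Cluster.SINGLE_COMPLICATION: 0.744,
    Cluster.MULTIPLE_COMPLICATIONS: 0.584,
}


class TestAccruals:
    def test_yfeod_immortal_and_all_cardiac(self, toy_immortal):
        trace = run_cohort(toy_immortal, Strategy.no_ert(), "male")
        assert accrue_yfeod(trace) == pytest.approx(70.0)
        # a cohort living entirely in the cardiac state accrues no YFEOD
        occ = np.zeros_like(trace.occupancy)
        occ[:, 4] = 1.0  # cardiac column
        trace.occupancy = occ
        assert accrue_yfeod(trace) == pytest.approx(0.0)

    def test_yfeod_linearity_in_occupancy(self, toy_immortal):
        trace = run_cohort(toy_immortal, Strategy.no_ert(), "male")
        occ = np.zeros_like(trace.occupancy)
        occ[1:11, 2] = 0.5  # symptoms
        occ[1:11, 5] = 0.5  # cva
        trace.occupancy = occ
        assert accrue_yfeod(trace) == pytest.approx(5.0)

    def test_qalys_immortal_asymptomatic_at_table_utility(self, toy_immortal):
        trace = run_cohort(toy_immortal, Strategy.no_ert(), "male")
        assert accrue_qalys(trace, FULL_UTILITIES) == pytest.approx(70 * 0.874)

    def test_unit_utility_equates_qalys_and_life_years(self, base_params):
        ones = {c: 1.0 for c in FULL_UTILITIES}
        tr = run_cohort(base_params, Strategy.no_ert(), "male")
        assert accrue_qalys(tr, ones) == pytest.approx(tr.total_life_years(), abs=1e-9)

    def test_zero_utility_gives_zero_qalys(self, toy_immortal):
        zeros = {c: 0.0 for c in FULL_UTILITIES}
        tr = run_cohort(toy_immortal, Strategy.no_ert(), "male")
        assert accrue_qalys(tr, zeros) == 0.0

    def test_missing_cluster_utility_raises(self, toy_immortal):
        tr = run_cohort(toy_immortal, Strategy.no_ert(), "male")
        with pytest.raises(KeyError, match="asymptomatic"):
            accrue_qalys(tr, {Cluster.ACRO_OR_SYMPTOMS: 0.5})

    def test_immortal_treated_cohort_accrues_70_drug_years(self, toy_immortal):
        trace = run_cohort(toy_immortal, TREAT_ALL, "male")
        assert trace.total_drug_cost() == pytest.approx(70 * 200_000.0)
        assert accrue_costs(trace, toy_immortal, TREAT_ALL) == pytest.approx(
            14_000_000.0
        )

    def test_untreated_cohort_has_zero_drug_cost(self, base_params):
        tr = run_cohort(base_params, Strategy.no_ert(), "female")
        assert tr.total_drug_cost() == 0.0

    def test_state_cost_discounting_matches_geometric_series(self):
        params = make_toy_params(
            cluster_costs={c: 100.0 for c in Cluster if c is not Cluster.DEAD},
            discount_rate_costs=0.04,
        )
        trace = run_cohort(params, Strategy.no_ert(), "male")
        r = 1 / 1.04
        expected = 100.0 * (1 - r**70) / (1 - r)
        assert accrue_costs(
            trace, params, Strategy.no_ert(), discounted=True
        ) == pytest.approx(expected, abs=1e-9)

    def test_helpers_agree_with_engine_accruals(self, base_params):
        strat = Strategy.ert_at_symptoms()
        tr = run_cohort(base_params, strat, "male")
        assert accrue_yfeod(tr) == pytest.approx(tr.total_yfeod(), abs=1e-9)
        utilities = {c: u.mean for c, u in base_params.utilities.items()}
        assert accrue_qalys(tr, utilities) == pytest.approx(
            tr.total_qalys(), abs=1e-9
        )
        assert accrue_costs(tr, base_params, strat) == pytest.approx(
            tr.total_cost(), rel=1e-12
        )


class TestStrategies:
    def test_no_ert_never_treats(self):
        s = Strategy.no_ert()
        assert not any(s.treats(st, a) for st in State for a in (0, 50))

    def test_at_symptoms_treats_from_symptomatic_stage(self):
        s = Strategy.ert_at_symptoms()
        assert s.treats(State.SYMPTOMS, 5)
        assert s.treats(State.ESRD_CARDIAC_CVA, 5)
        assert not s.treats(State.ASYMPTOMATIC, 5)
        assert not s.treats(State.ACROPARESTHESIA, 5)
        assert not s.treats(State.DEATH, 5)

    def test_at_40_requires_age(self):
        s = Strategy.ert_at_40()
        assert not s.treats(State.SYMPTOMS, 39)
        assert s.treats(State.SYMPTOMS, 40)

    def test_stop_after_two_complications(self):
        s = Strategy.ert_stop_after_2()
        assert s.treats(State.CARDIAC, 50)
        assert not s.treats(State.CARDIAC_CVA, 50)

    def test_unknown_rule_raises(self):
        with pytest.raises(ValueError):
            Strategy.from_rule("at-breakfast")


class TestNullEffect:
    def test_traces_identical_except_drug_cost(self, null_params):
        ert = run_cohort(null_params, Strategy.ert_at_symptoms(), "male")
        no = run_cohort(null_params, Strategy.no_ert(), "male")
        assert np.array_equal(ert.occupancy, no.occupancy)
        assert ert.total_qalys() == no.total_qalys()
        assert ert.total_drug_cost() > 0 and no.total_drug_cost() == 0.0


class TestSexMix:
    def test_mixed_result_is_weighted_average_of_sexes(self, base_params):
        out = evaluate_strategy(base_params, Strategy.ert_at_symptoms())
        w = base_params.sex_mix
        for attr in ("yfeod", "qalys", "cost", "cost_disc", "drug_cost"):
            mixed = getattr(out["all"], attr)
            manual = w * getattr(out["male"], attr) + (1 - w) * getattr(
                out["female"], attr
            )
            assert mixed == pytest.approx(manual, abs=1e-12)


class TestTreatmentDominance:
    def test_treated_yfeod_at_least_untreated(self, base_params):
        res = compare_strategies(base_params, Strategy.ert_at_symptoms())
        for group in ("all", "male", "female"):
            d = res.delta(group)
            assert d.yfeod >= 0.0
            assert d.qalys >= 0.0


class TestMicrosim:
    def test_deterministic_under_seed(self, base_params):
        a = run_microsim(base_params, Strategy.ert_at_symptoms(), 1, seed=42)
        b = run_microsim(base_params, Strategy.ert_at_symptoms(), 1, seed=42)
        assert a.per_patient["qalys"][0] == b.per_patient["qalys"][0]
        assert a.per_patient["cost"][0] == b.per_patient["cost"][0]

    def test_immortal_toy_gives_70_alive_cycles_every_time(self, toy_immortal):
        res = run_microsim(toy_immortal, Strategy.no_ert(), 50, seed=0)
        assert np.all(res.per_patient["life_years"] == 70.0)

    def test_mean_converges_to_cohort(self, base_params):
        cohort = evaluate_strategy(base_params, Strategy.no_ert())["all"]
        res = run_microsim(base_params, Strategy.no_ert(), 20_000, seed=11)
        assert abs(res.yfeod - cohort.yfeod) < 2.5 * res.se("yfeod")

    def test_error_shrinks_with_sample_size(self, base_params):
        """Monte-Carlo error scales like 1/sqrt(n): quadrupling n roughly
        halves the RMSE around the cohort expectation."""
        cohort = evaluate_strategy(base_params, Strategy.no_ert())["all"].yfeod
        rmse = {}
        for n in (250, 1000, 4000):
            errs = [
                run_microsim(base_params, Strategy.no_ert(), n, seed=100 + r).yfeod
                - cohort
                for r in range(12)
            ]
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[250] / rmse[1000] == pytest.approx(2.0, rel=0.6)
        assert rmse[1000] / rmse[4000] == pytest.approx(2.0, rel=0.6)

    def test_common_random_numbers_share_paths(self, null_params):
        """With a null effect and shared uniforms, both arms walk identical
        paths patient by patient."""
        rng = np.random.default_rng(5)
        sexes = np.where(rng.random(200) < 0.5, "male", "female")
        uniforms = rng.random((200, null_params.horizon))
        a = microsimulate_outcomes(null_params, Strategy.ert_at_symptoms(), sexes, uniforms)
        b = microsimulate_outcomes(null_params, Strategy.no_ert(), sexes, uniforms)
        assert np.array_equal(a.per_patient["qalys"], b.per_patient["qalys"])

    def test_requires_at_least_one_patient(self, base_params):
        with pytest.raises(ValueError):
            run_microsim(base_params, Strategy.no_ert(), 0)
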