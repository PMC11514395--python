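"""Markov engine: mortality fitting, matrix construction, cohort rewards."""
import numpy as np
import pytest

from pgxcea.markov import (MortalityCurve, STATES, build_transition_matrix,
                           compare_long_term, fit_mortality_curve,
                           per_cycle_probability, run_cohort)
from pgxcea.params import Strategy
from pgxcea.synthetic import SyntheticSpec, random_parameter_set


def _frozen(ps, **rates):
    """as-printed parameter set with every transition overridden."""
    ps = ps.copy()
    ps.markov.variant = "as_printed"
    defaults = dict(to_response=0.0, to_relapse_0=0.0, to_relapse_1=0.0,
                    to_no_response=0.0, suicide_death=0.0, nonsuicide_death=0.0)
    defaults.update(rates)
    updates = {}
    for strat in Strategy:
        b = f"markov.transition.{strat.value}"
        updates.update({
            f"{b}.to_response": defaults["to_response"],
            f"{b}.to_relapse.0": defaults["to_relapse_0"],
            f"{b}.to_relapse.1": defaults["to_relapse_1"],
            f"{b}.to_no_response": defaults["to_no_response"],
            f"{b}.suicide_death": defaults["suicide_death"],
            f"{b}.nonsuicide_death": defaults["nonsuicide_death"],
        })
    return ps.with_values(updates)


class TestPerCycleProbability:
    @pytest.mark.parametrize("p_annual, cycle, expected", [
        (0.0, 0.25, 0.0),
        (1.0, 0.25, 1.0),
        (0.04, 0.25, 1 - 0.96 ** 0.25),
    ])
    def test_closed_form(self, p_annual, cycle, expected):
        assert per_cycle_probability(p_annual, cycle) == pytest.approx(expected,
                                                                       abs=1e-12)

    def test_rate_conversion_magnitude(self):
        # a 4%/yr risk is ~1.015% per quarter
        assert per_cycle_probability(0.04, 0.25) == pytest.approx(0.010152, abs=5e-6)

    @pytest.mark.parametrize("bad", [(-0.1, 0.25), (1.1, 0.25), (0.5, 0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            per_cycle_probability(*bad)


class TestMortalityCurve:
    def test_exact_quadratic_recovered(self):
        coefs = np.array([0.05, -0.002, 0.00003])  # ascending powers
        ages = np.arange(45, 90, 5)
        rates = np.polynomial.polynomial.polyval(ages, coefs)
        curve = fit_mortality_curve(list(zip(ages, rates)), degree=2)
        assert np.allclose(curve.coefficients, coefs, atol=1e-9)

    def test_constant_rates_give_flat_curve(self):
        curve = fit_mortality_curve([(a, 0.01) for a in (50, 60, 70)], degree=2)
        assert curve(55.0) == pytest.approx(0.01, abs=1e-9)

    def test_degree_zero_is_mean(self):
        curve = fit_mortality_curve([(50, 0.01), (60, 0.03), (70, 0.08)], degree=0)
        assert curve(62.0) == pytest.approx((0.01 + 0.03 + 0.08) / 3, abs=1e-12)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mortality_curve([(50, 0.01), (60, 0.02)], degree=2)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_mortality_curve([(50, 0.01), (60, 1.5), (70, 0.1)], degree=1)

    def test_evaluation_clamped(self):
        curve = MortalityCurve(np.array([-1.0, 0.0]), 1)
        assert curve(50.0) == 0.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("variant", ["reconciled", "as_printed"])
    def test_rows_sum_to_one_and_deaths_absorb(self, base_ps, variant):
        ps = base_ps.copy()
        ps.markov.variant = variant
        for strat in Strategy:
            M = build_transition_matrix(strat, 60.0, ps)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M[3, 3] == 1.0 and M[4, 4] == 1.0
            assert (M >= 0).all()

    def test_mortality_rises_with_age_when_trended(self, base_ps):
        m50 = build_transition_matrix(Strategy.PGX, 50.0, base_ps)
        m80 = build_transition_matrix(Strategy.PGX, 80.0, base_ps)
        assert m80[0, 4] > m50[0, 4]

    def test_age_trend_off_freezes_start_age(self, base_ps):
        frozen = build_transition_matrix(Strategy.PGX, 80.0, base_ps,
                                         age_trends=False)
        at_start = build_transition_matrix(Strategy.PGX, base_ps.markov.start_age,
                                           base_ps)
        assert frozen[0, 4] == pytest.approx(at_start[0, 4], abs=1e-15)

    def test_as_printed_uses_table_verbatim(self, base_ps):
        ps = base_ps.copy()
        ps.markov.variant = "as_printed"
        M = build_transition_matrix(Strategy.PGX, 60.0, ps)
        tr = ps.markov.transitions[Strategy.PGX]
        assert M[0, 1] == pytest.approx(tr.relapse_total)
        assert M[1, 3] == pytest.approx(tr.suicide_death)
        assert M[0, 4] == pytest.approx(tr.nonsuicide_death)
        assert M[0, 3] == 0.0  # suicide death only from the failure states

    def test_overfull_row_renormalized_with_warning(self, base_ps, caplog):
        ps = base_ps.with_values({
            "markov.transition.PGX.to_relapse.0": 0.7,
            "markov.transition.PGX.to_no_response": 0.7})
        ps.markov.variant = "as_printed"
        with caplog.at_level("WARNING"):
            M = build_transition_matrix(Strategy.PGX, 60.0, ps)
        assert "renormalizing" in caplog.text
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)


class TestCohortRewards:
    def test_no_transitions_no_discount_gives_full_horizon(self, base_ps):
        ps = _frozen(base_ps)
        trace = run_cohort(Strategy.PGX, ps, discount_on=False)
        assert trace.ly == pytest.approx(33.0, abs=1e-9)
        # all time in response: QALY integrates the age-banded utility
        u = base_ps.utilities
        expected_qaly = 0.25 * sum(u.response(48 + 0.25 * t) for t in range(132))
        assert trace.qaly == pytest.approx(expected_qaly, abs=1e-9)

    def test_immediate_death_leaves_one_cycle_reward(self, base_ps):
        ps = _frozen(base_ps, nonsuicide_death=1.0)
        trace = run_cohort(Strategy.PGX, ps, discount_on=False)
        assert trace.ly == pytest.approx(0.25, abs=1e-12)
        assert trace.qaly == pytest.approx(0.25 * base_ps.utilities.response(48.0),
                                           abs=1e-12)

    def test_half_cycle_removes_half_of_first_and_last_cycle(self, base_ps):
        ps = _frozen(base_ps)  # constant occupancy
        full = run_cohort(Strategy.PGX, ps, discount_on=False, half_cycle=False)
        half = run_cohort(Strategy.PGX, ps, discount_on=False, half_cycle=True)
        # first and last cycle each contribute 0.25 LY; half weight drops 0.25 total
        assert full.ly - half.ly == pytest.approx(0.25, abs=1e-12)

    def test_occupancy_conserved_and_absorbing_monotone(self, base_ps):
        for strat in Strategy:
            trace = run_cohort(strat, base_ps)
            occ = trace.records[[s.lower() for s in STATES]].to_numpy()
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            dead = occ[:, 3] + occ[:, 4]
            assert (np.diff(dead) >= -1e-15).all()

    def test_event_costs_follow_incident_transitions(self, base_ps):
        ps = _frozen(base_ps, nonsuicide_death=1.0)
        trace = run_cohort(Strategy.SOC, ps, discount_on=False)
        # one cycle of recurring costs + one non-suicide death per person
        lt = ps.long_costs
        expected = (lt.acquisition[Strategy.SOC] + lt.lab_screening
                    + lt.follow_up + lt.event_nonsuicide_death)
        assert trace.total_cost == pytest.approx(expected, abs=1e-9)


class TestMonotonicity:
    def test_discounting_reduces_totals(self, base_ps):
        disc = run_cohort(Strategy.PGX, base_ps, discount_on=True)
        undisc = run_cohort(Strategy.PGX, base_ps, discount_on=False)
        assert disc.ly <= undisc.ly
        assert disc.qaly <= undisc.qaly
        assert disc.total_cost <= undisc.total_cost

    def test_qaly_never_exceeds_ly(self, base_ps):
        for strat in Strategy:
            t = run_cohort(strat, base_ps)
            assert t.qaly <= t.ly

    def test_five_year_horizon_bounded_by_lifetime(self, base_ps):
        for strat in Strategy:
            short = run_cohort(strat, base_ps, horizon_years=5.0)
            life = run_cohort(strat, base_ps)
            assert short.ly <= life.ly
            assert short.qaly <= life.qaly
            assert short.total_cost <= life.total_cost

    def test_raising_utility_weakly_raises_qaly(self, base_ps):
        bumped = base_ps.with_values({"utility.no_response": 0.6})
        assert run_cohort(Strategy.SOC, bumped).qaly >= \
            run_cohort(Strategy.SOC, base_ps).qaly

    def test_raising_suicide_death_weakly_lowers_ly(self, base_ps):
        ps = base_ps.copy()
        ps.markov.variant = "as_printed"
        worse = ps.with_values({"markov.transition.SOC.suicide_death": 0.3})
        assert run_cohort(Strategy.SOC, worse).ly <= run_cohort(Strategy.SOC, ps).ly


class TestConservationProperty:
    def test_random_synthetic_sets_conserve_occupancy(self):
        for seed in range(60):
            ps = random_parameter_set(SyntheticSpec(seed=seed))
            trace = run_cohort(Strategy.PGX, ps)
            occ = trace.records[[s.lower() for s in STATES]].to_numpy()
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)


class TestCompareLongTerm:
    def test_identical_strategy_blocks_give_zero_increments(self, base_ps):
        flat = base_ps.flatten()
        updates = {pid.replace(".PGX", ".SOC"): val for pid, val in flat.items()
                   if ".PGX" in pid}
        ps2 = base_ps.with_values(updates)
        cmp = compare_long_term(ps2)
        assert cmp.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert cmp.delta_effects["ly"] == pytest.approx(0.0, abs=1e-12)
        assert cmp.delta_effects["qaly"] == pytest.approx(0.0, abs=1e-12)

    def test_base_case_pgx_dominates(self, base_ps):
        cmp = compare_long_term(base_ps)
        assert cmp.saving > 0
        assert cmp.delta_effects["ly"] > 0
        assert cmp.outcomes["qaly"].label.value == "DOMINANT"

    def test_category_deltas_sum_to_total(self, base_ps):
        cmp = compare_long_term(base_ps)
        assert sum(cmp.detail["category_deltas"].values()) == \
            pytest.approx(cmp.delta_cost, rel=1e-12)
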