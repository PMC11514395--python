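"""Distribution fitting, PSA machinery, CEAC and tornado regression."""
import numpy as np
import pandas as pd
import pytest

from pgxcea.params import Strategy
from pgxcea.tree import compare_short_term, strategy_outcomes
from pgxcea.markov import compare_long_term, run_cohort
from pgxcea.uncertainty import (DistributionSpec, Family, _markov_vec,
                                _sample_matrix, _tree_vec, beta_from_mean_ci,
                                ceac, default_distribution_specs,
                                gamma_from_mean_ci, run_psa,
                                sample_parameter_set, tornado_regression,
                                univariate_sweep)


class TestBetaFit:
    def test_symmetric_interval_gives_equal_shapes(self):
        a, b = beta_from_mean_ci(0.5, 0.4, 0.6)
        assert a == pytest.approx(b, rel=1e-12)

    def test_mean_round_trip(self):
        a, b = beta_from_mean_ci(0.37, 0.30, 0.44)
        assert a / (a + b) == pytest.approx(0.37, abs=1e-9)

    def test_overdispersed_interval_rejected(self):
        # a near-unit-width interval around an extreme mean implies a
        # variance no beta distribution can carry
        with pytest.raises(ValueError, match="no beta"):
            beta_from_mean_ci(0.02, 0.0001, 0.9999)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            beta_from_mean_ci(0.5, 0.6, 0.7)


class TestGammaFit:
    def test_mean_round_trip(self):
        shape, scale = gamma_from_mean_ci(540.0, 405.0, 675.0)
        assert shape * scale == pytest.approx(540.0, abs=1e-9)

    def test_min_cv_floor_guards_degenerate_interval(self):
        shape, scale = gamma_from_mean_ci(100.0, 100.0, 100.0)
        assert np.isfinite(shape)
        assert shape == pytest.approx(1.0 / 0.01 ** 2)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_mean_ci(0.0, 0.0, 1.0)

    def test_sampled_mean_close_at_large_n(self):
        shape, scale = gamma_from_mean_ci(954.0, 477.0, 1431.0)
        draws = np.random.default_rng(7).gamma(shape, scale, 1_000_000)
        assert draws.mean() == pytest.approx(954.0, rel=0.01)


class TestSampleParameterSet:
    def test_all_fixed_is_identity(self, base_ps):
        specs = [DistributionSpec(pid, Family.FIXED, v)
                 for pid, v in base_ps.flatten().items()]
        out = sample_parameter_set(base_ps, specs, seed=3)
        assert out.flatten() == base_ps.flatten()

    def test_same_seed_reproduces(self, base_ps):
        specs = default_distribution_specs(base_ps)
        a = sample_parameter_set(base_ps, specs, seed=11)
        b = sample_parameter_set(base_ps, specs, seed=11)
        assert a.flatten() == b.flatten()

    def test_fixed_prevalences_untouched(self, base_ps):
        specs = default_distribution_specs(base_ps)
        out = sample_parameter_set(base_ps, specs, seed=5)
        for pid, v in base_ps.flatten().items():
            if pid.startswith("prevalence."):
                assert out.flatten()[pid] == v

    def test_unknown_parameter_rejected(self, base_ps):
        with pytest.raises(KeyError):
            sample_parameter_set(
                base_ps, [DistributionSpec("not.a.param", Family.FIXED, 1.0)], 0)

    def test_beta_empirical_mean(self):
        spec = DistributionSpec("x", Family.BETA, 0.37,
                                0.37 * 0.8, 0.37 * 1.2)
        rng = np.random.default_rng(0)
        from pgxcea.uncertainty import _draw
        draws = _draw(spec, rng, 100_000)
        assert draws.mean() == pytest.approx(0.37, abs=0.005)


class TestVectorizedEvaluators:
    """The PSA evaluators must agree exactly with the reference paths."""

    @pytest.mark.parametrize("variant", ["reconciled", "as_printed"])
    def test_tree_and_markov_match_reference(self, base_ps, variant):
        ps = base_ps.copy()
        ps.markov.variant = variant
        specs = default_distribution_specs(ps)
        n = 4
        vals = _sample_matrix(specs, n, seed=42)
        for strat in Strategy:
            p_no, p_any, cost_s = _tree_vec(strat, ps, vals, n)
            ly, qaly, cost_l = _markov_vec(strat, ps, vals, n)
            for i in range(n):
                psi = ps.with_values({k: float(v[i]) for k, v in vals.items()})
                ref = strategy_outcomes(strat, psi)
                trace = run_cohort(strat, psi)
                assert p_no[i] == pytest.approx(ref.p_success_no_se, abs=1e-12)
                assert p_any[i] == pytest.approx(ref.p_success_any_se, abs=1e-12)
                assert cost_s[i] == pytest.approx(ref.expected_cost, abs=1e-8)
                assert ly[i] == pytest.approx(trace.ly, abs=1e-10)
                assert qaly[i] == pytest.approx(trace.qaly, abs=1e-10)
                assert cost_l[i] == pytest.approx(trace.total_cost, abs=1e-6)


class TestRunPSA:
    def test_single_all_fixed_draw_equals_base_case(self, base_ps):
        specs = [DistributionSpec(pid, Family.FIXED, v)
                 for pid, v in base_ps.flatten().items()]
        res = run_psa(base_ps, specs, n=1, seed=0)
        short = compare_short_term(base_ps)
        long = compare_long_term(base_ps)
        row = res.draws.iloc[0]
        assert row.d_cost_short == pytest.approx(short.delta_cost, abs=1e-9)
        assert row.d_cost_long == pytest.approx(long.delta_cost, abs=1e-6)
        assert row.d_ly == pytest.approx(long.delta_effects["ly"], abs=1e-10)

    def test_master_seed_bitwise_reproducible(self, base_ps):
        specs = default_distribution_specs(base_ps)
        a = run_psa(base_ps, specs, n=200, seed=9)
        b = run_psa(base_ps, specs, n=200, seed=9)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_growing_n_preserves_early_draws(self, base_ps):
        specs = default_distribution_specs(base_ps)
        small = run_psa(base_ps, specs, n=50, seed=9)
        big = run_psa(base_ps, specs, n=120, seed=9)
        pd.testing.assert_frame_equal(small.draws,
                                      big.draws.iloc[:50].reset_index(drop=True))

    def test_degenerate_specs_force_total_dominance(self, base_ps):
        # huge SoC-only cost makes every draw cheaper and better under PGx
        ps = base_ps.with_values({"cost.long.acquisition.SOC": 1e6})
        specs = [DistributionSpec(pid, Family.FIXED, v)
                 for pid, v in ps.flatten().items()]
        res = run_psa(ps, specs, n=3, seed=0)
        assert res.draws.dominant_long.all()


class TestCEAC:
    def test_all_dominant_draws_give_unit_curve(self):
        curve = ceac([-10.0, -5.0], [0.1, 0.2], [0.0, 1e5, 1e6])
        assert (curve.p_acceptable == 1.0).all()

    def test_zero_wtp_counts_cost_savings(self):
        dc = np.array([-1.0, 2.0, -3.0, 4.0])
        de = np.ones(4)
        curve = ceac(dc, de, [0.0])
        assert curve.p_acceptable.iloc[0] == pytest.approx(0.5)

    def test_bounded_and_uses_every_draw(self):
        rng = np.random.default_rng(1)
        curve = ceac(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000),
                     np.linspace(0, 5, 11))
        assert ((curve.p_acceptable >= 0) & (curve.p_acceptable <= 1)).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac([1.0], [1.0], [])

    def test_matches_bivariate_normal_closed_form(self):
        from scipy.stats import norm
        rng = np.random.default_rng(2024)
        mu_c, mu_e, sd_c, sd_e, rho = 500.0, 0.05, 2000.0, 0.04, 0.3
        cov = [[sd_c ** 2, rho * sd_c * sd_e], [rho * sd_c * sd_e, sd_e ** 2]]
        draws = rng.multivariate_normal([mu_c, mu_e], cov, size=100_000)
        grid = np.array([0.0, 1e4, 5e4, 1e5, 5e5])
        curve = ceac(draws[:, 0], draws[:, 1], grid)
        for w, p in zip(grid, curve.p_acceptable):
            mean = w * mu_e - mu_c
            sd = np.sqrt(w ** 2 * sd_e ** 2 + sd_c ** 2 - 2 * w * rho * sd_c * sd_e)
            assert p == pytest.approx(norm.cdf(mean / sd), abs=0.01)


class TestTornado:
    def test_planted_linear_model_recovered(self):
        rng = np.random.default_rng(3)
        n = 20_000
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = 2 * x1 + 1 * x2 + rng.normal(0, 0.1, n)
        entries = tornado_regression(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert entries[0].param_id == "x1"
        assert entries[0].rank == 1
        sd_y = y.std()
        assert entries[0].coefficient == pytest.approx(2 / sd_y, rel=0.02)
        assert entries[1].coefficient == pytest.approx(1 / sd_y, rel=0.05)

    def test_single_input_coefficient_is_unity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 5000)
        entries = tornado_regression(pd.DataFrame({"x": x}), 3 * x + 1)
        assert abs(entries[0].coefficient) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 1000)
        df = pd.DataFrame({"x": x, "const": np.ones(1000)})
        with pytest.warns(UserWarning, match="const"):
            entries = tornado_regression(df, x)
        assert [e.param_id for e in entries] == ["x"]

    def test_base_psa_ranks_genotyping_cost_for_short_term_saving(self, base_ps):
        specs = default_distribution_specs(base_ps)
        res = run_psa(base_ps, specs, n=4000, seed=17)
        entries = tornado_regression(res.inputs, -res.draws.d_cost_short)
        top = [e.param_id for e in entries[:8]]
        assert "cost.short.genotyping_panel" in top


class TestUnivariateSweep:
    def test_zero_fraction_returns_base(self, base_ps):
        base = compare_short_term(base_ps).saving
        low, high = univariate_sweep(base_ps, "cost.short.genotyping_panel",
                                     lambda p: compare_short_term(p).saving,
                                     fraction=0.0)
        assert low == pytest.approx(base) and high == pytest.approx(base)

    def test_genotyping_sweep_width_matches_linearity(self, base_ps):
        # the endpoint is linear in the fee: +-25% of 540 moves it by -+135
        low, high = univariate_sweep(base_ps, "cost.short.genotyping_panel",
                                     lambda p: compare_short_term(p).saving)
        assert low - high == pytest.approx(2 * 0.25 * 540.0, abs=1e-9)

    def test_discount_rate_sweep_brackets_base(self, base_ps):
        base = compare_long_term(base_ps).saving
        low, high = univariate_sweep(base_ps, "markov.discount_rate",
                                     lambda p: compare_long_term(p).saving)
        assert min(low, high) <= base <= max(low, high)

    def test_unknown_parameter_rejected(self, base_ps):
        with pytest.raises(KeyError):
            univariate_sweep(base_ps, "bogus", lambda p: 0.0)
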