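"""One-way (tornado) and probabilistic sensitivity analyses."""

import numpy as np
import pytest
from scipy import stats

import oncocea as oc
from oncocea.sensitivity import tornado_table


def _toy_model(overrides):
    """Closed-form toy: ICER = x / u with defaults x=100, u=0.5."""
    x = overrides.get("x", 100.0)
    u = overrides.get("u", 0.5)
    return oc.compare_values(x, 1.0 + u, 0.0, 1.0, wtp=150_000.0)


TOY_PARAMS = [
    oc.ParameterDef("x", 100.0, "cost"),
    oc.ParameterDef("u", 0.5, "utility"),
    oc.ParameterDef("inert", 5.0, "cost"),  # not read by the model
]


class TestBounds:
    def test_cost_bounds_are_plus_minus_25_percent(self):
        p = oc.ParameterDef("costs.drugs_per_mg.osimertinib", 7.08, "cost")
        assert oc.dsa_bounds(p) == pytest.approx((5.31, 8.85))

    def test_utility_bounds_are_plus_minus_10_percent(self):
        p = oc.ParameterDef("utilities.pfs", 0.71, "utility")
        assert oc.dsa_bounds(p) == pytest.approx((0.639, 0.781))

    def test_utility_upper_bound_capped_at_one(self):
        p = oc.ParameterDef("utilities.x", 0.95, "utility")
        assert oc.dsa_bounds(p)[1] == 1.0

    def test_discount_bounds_span_zero_to_eight_percent(self):
        p = oc.ParameterDef("economics.annual_discount", 0.03, "discount")
        assert oc.dsa_bounds(p) == (0.0, 0.08)

    def test_explicit_ci_overrides_derived_bounds(self):
        p = oc.ParameterDef("clinical.hr_os.point", 0.75, "hazard_ratio",
                            low=0.57, high=0.97)
        assert oc.dsa_bounds(p) == (0.57, 0.97)

    def test_default_config_enumeration_covers_table(self):
        defs = oc.build_parameter_defs(oc.default_config())
        names = {d.name for d in defs}
        assert "costs.drugs_per_mg.osimertinib" in names
        assert "clinical.hr_os.point" in names
        assert "utilities.pfs" in names
        assert "profile.bsa" in names
        assert len(defs) > 30


class TestTornado:
    def test_toy_spreads_match_hand_computed_values(self):
        entries = oc.run_dsa(_toy_model, TOY_PARAMS)
        by_name = {e.parameter: e for e in entries}
        assert by_name["x"].icer_at_low == pytest.approx(75 / 0.5)
        assert by_name["x"].icer_at_high == pytest.approx(125 / 0.5)
        assert by_name["x"].spread == pytest.approx(100.0)
        assert by_name["u"].icer_at_low == pytest.approx(100 / 0.45)
        assert by_name["u"].icer_at_high == pytest.approx(100 / 0.55)
        assert by_name["u"].spread == pytest.approx(100 / 0.45 - 100 / 0.55)

    def test_inert_parameter_has_zero_spread(self):
        entries = oc.run_dsa(_toy_model, TOY_PARAMS)
        inert = next(e for e in entries if e.parameter == "inert")
        assert inert.spread == 0.0
        assert not inert.flagged

    def test_entries_sorted_by_spread_descending(self):
        entries = oc.run_dsa(_toy_model, TOY_PARAMS)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_raising_intervention_only_cost_raises_icer_monotonically(self):
        icers = [_toy_model({"x": x}).icer for x in (80, 100, 120)]
        assert icers == sorted(icers)

    def test_model_failure_is_flagged_not_dropped(self):
        def broken(overrides):
            if overrides.get("x", 100.0) > 110:
                raise RuntimeError("boom")
            return _toy_model(overrides)

        entries = oc.run_dsa(broken, TOY_PARAMS[:1])
        assert len(entries) == 1
        assert entries[0].flagged
        assert np.isnan(entries[0].icer_at_high)

    def test_table_columns(self):
        df = tornado_table(oc.run_dsa(_toy_model, TOY_PARAMS))
        assert list(df.columns) == ["parameter", "icer_low", "icer_high",
                                    "spread", "flagged"]


class TestSampling:
    def test_gamma_mean_matches_baseline(self):
        p = oc.ParameterDef("c", 7.08, "cost")
        rng = np.random.default_rng(1)
        draws = [oc.sample_parameters([p], rng)["c"] for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(7.08, rel=0.01)
        assert np.std(draws) == pytest.approx(0.708, rel=0.05)

    def test_beta_draws_stay_in_unit_interval(self):
        p = oc.ParameterDef("u", 0.71, "utility")
        rng = np.random.default_rng(2)
        draws = np.array([oc.sample_parameters([p], rng)["u"]
                          for _ in range(5000)])
        assert np.all((draws > 0) & (draws < 1))
        assert np.mean(draws) == pytest.approx(0.71, rel=0.02)

    def test_infeasible_beta_moments_fall_back_to_uniform(self):
        p = oc.ParameterDef("u", 0.995, "proportion")
        rng = np.random.default_rng(3)
        draws = np.array([oc.sample_parameters([p], rng)["u"]
                          for _ in range(2000)])
        assert np.all((draws >= 0.995 * 0.9) & (draws <= 1.0))

    def test_lognormal_hr_median_at_point_estimate(self):
        p = oc.ParameterDef("hr", 0.75, "hazard_ratio", low=0.57, high=0.97)
        rng = np.random.default_rng(4)
        draws = np.array([oc.sample_parameters([p], rng)["hr"]
                          for _ in range(20_000)])
        assert np.median(draws) == pytest.approx(0.75, rel=0.01)
        log_sd = (np.log(0.97) - np.log(0.57)) / 3.92
        assert np.std(np.log(draws)) == pytest.approx(log_sd, rel=0.05)

    def test_zero_sd_degenerates_to_baseline(self):
        rng = np.random.default_rng(5)
        draw = oc.sample_parameters(TOY_PARAMS, rng, sd_frac=0.0)
        assert draw == {"x": 100.0, "u": 0.5, "inert": 5.0}

    def test_draws_reproducible_under_seed(self):
        a = oc.sample_parameters(TOY_PARAMS, np.random.default_rng(9))
        b = oc.sample_parameters(TOY_PARAMS, np.random.default_rng(9))
        assert a == b


class TestPSA:
    def test_degenerate_psa_reproduces_base_case(self):
        res = oc.run_psa(_toy_model, TOY_PARAMS, n_reps=50, seed=0,
                         sd_frac=0.0)
        base = _toy_model({})
        assert np.all(res.delta_cost == base.delta_cost)
        assert np.all(res.delta_qaly == base.delta_qaly)

    def test_degenerate_ceac_is_step_at_base_icer(self):
        res = oc.run_psa(_toy_model, TOY_PARAMS, n_reps=50, seed=0,
                         sd_frac=0.0)
        base_icer = _toy_model({}).icer  # 200 $/QALY
        ceac = res.ceac(np.array([base_icer * 0.5, base_icer * 2.0]))
        assert list(ceac["probability"]) == [0.0, 1.0]

    def test_ceac_matches_analytic_probability(self):
        """Only cost x ~ gamma(mean 100, sd 10) varies, so
        P(cost-effective at w) = P(x < 0.5 w) in closed form."""
        params = [oc.ParameterDef("x", 100.0, "cost")]
        n = 5000
        res = oc.run_psa(_toy_model, params, n_reps=n, seed=7)
        shape, scale = 100.0, 1.0
        for wtp in (180.0, 200.0, 220.0):
            analytic = stats.gamma.cdf(0.5 * wtp, shape, scale=scale)
            se = np.sqrt(analytic * (1 - analytic) / n)
            assert abs(res.probability_cost_effective(wtp)
                       - analytic) <= 3 * max(se, 1e-3)

    def test_ceac_from_stored_samples_equals_online(self):
        res = oc.run_psa(_toy_model, TOY_PARAMS, n_reps=200, seed=11)
        grid = np.array([100.0, 200.0, 300.0])
        stored = [(g * res.delta_qaly - res.delta_cost > 0).mean()
                  for g in grid]
        assert list(res.ceac(grid)["probability"]) == stored

    def test_psa_bit_reproducible(self):
        a = oc.run_psa(_toy_model, TOY_PARAMS, n_reps=100, seed=13)
        b = oc.run_psa(_toy_model, TOY_PARAMS, n_reps=100, seed=13)
        assert np.array_equal(a.cost_a, b.cost_a)
        assert np.array_equal(a.qaly_a, b.qaly_a)

    def test_failed_replicates_counted_and_excluded(self):
        calls = {"n": 0}

        def flaky(overrides):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("diverged")
            return _toy_model(overrides)

        res = oc.run_psa(flaky, TOY_PARAMS, n_reps=50, seed=1)
        assert res.n_failed == 10
        assert res.n_reps == 40

    def test_limit_ceac_approaches_positive_qaly_gain_fraction(self):
        res = oc.run_psa(_toy_model, TOY_PARAMS, n_reps=200, seed=3)
        assert res.probability_cost_effective(1e12) == pytest.approx(
            (res.delta_qaly > 0).mean())
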