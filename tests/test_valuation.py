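"""Dosing arithmetic, per-cycle costing, discounted accumulation."""

import copy

import numpy as np
import pytest

import oncocea as oc
from oncocea.markov_engine import CYCLE_MONTHS
from oncocea.valuation import StrategyValuation

PROFILE = oc.PatientProfile(weight=70, bsa=1.86, ccr=70, age=65)


def test_dose_rules():
    assert oc.drug_dose_mg("per_m2", 500.0, PROFILE) == pytest.approx(930.0)
    assert oc.drug_dose_mg("calvert", 5.0, PROFILE) == pytest.approx(475.0)
    assert oc.drug_dose_mg("per_m2", 75.0, PROFILE) == pytest.approx(139.5)
    assert oc.drug_dose_mg("flat_daily", 80.0, PROFILE) == 80.0
    assert oc.drug_dose_mg("per_kg", 15.0, PROFILE) == pytest.approx(1050.0)
    with pytest.raises(ValueError, match="unknown dosing rule"):
        oc.drug_dose_mg("per_fortnight", 1.0, PROFILE)


def test_profile_rejects_nonpositive_values():
    with pytest.raises(ValueError):
        oc.PatientProfile(weight=0.0)


def _zero_discontinuation_config():
    cfg = oc.default_config()
    for k in cfg["clinical"]["discontinuation"]["combo"]:
        cfg["clinical"]["discontinuation"]["combo"][k] = 0.0
    cfg["clinical"]["discontinuation"]["mono"]["osimertinib"] = 0.0
    return cfg


def test_first_line_cycle_cost_components():
    """With discontinuation off, induction cost decomposes into
    osimertinib 80 mg/day x 21 d x $7.08, pemetrexed 930 mg x $0.32,
    carboplatin 475 mg x $0.28, and a 2-hour infusion fee."""
    cfg = _zero_discontinuation_config()
    vals = oc.build_strategy_valuations(cfg)
    osi = 80 * 21 * 7.08
    pem = 930 * 0.32
    carbo = 475 * 0.28
    infusion_2h = 132.16 + 28.47
    assert osi == pytest.approx(11_894.40)
    assert pem == pytest.approx(297.60)
    assert infusion_2h == pytest.approx(160.63)
    assert vals["combo"].first_line_induction == pytest.approx(
        osi + pem + carbo + infusion_2h)
    assert vals["combo"].first_line_maintenance == pytest.approx(
        osi + pem + 132.16)
    assert vals["mono"].first_line_induction == pytest.approx(osi)


def test_discontinuation_scales_each_agent():
    cfg = oc.default_config()
    vals = oc.build_strategy_valuations(cfg)
    osi = 80 * 21 * 7.08
    assert vals["mono"].first_line_induction == pytest.approx(
        osi * (1 - 0.5527))
    expected_combo = (osi * (1 - 0.4420) + 297.60 * (1 - 0.7536)
                      + 475 * 0.28 * (1 - 0.2319) + 160.63)
    assert vals["combo"].first_line_induction == pytest.approx(expected_combo)


def test_cisplatin_option_prices_by_body_surface():
    cfg = _zero_discontinuation_config()
    cfg["regimen"]["platinum_agent"] = "cisplatin"
    vals = oc.build_strategy_valuations(cfg)
    carbo_cfg = _zero_discontinuation_config()
    delta = (vals["combo"].first_line_induction
             - oc.build_strategy_valuations(carbo_cfg)["combo"]
             .first_line_induction)
    assert delta == pytest.approx(139.5 * 0.22 - 475 * 0.28)


def test_followup_and_imaging_cycle_shares():
    vals = oc.build_strategy_valuations(oc.default_config())
    expected = 542.65 * 21 / 30.4375 + 114.54 * 21 / 91.3125
    assert vals["mono"].background_per_cycle == pytest.approx(expected)


def test_negative_cost_rejected():
    cfg = oc.default_config()
    cfg["costs"]["drugs_per_mg"]["osimertinib"] = -1.0
    with pytest.raises(ValueError, match="negative cost"):
        oc.build_strategy_valuations(cfg)


def test_sae_swap_flag_exchanges_arm_burdens():
    cfg = oc.default_config()
    plain = oc.build_strategy_valuations(cfg)
    cfg["sae_risks"]["swap_arms"] = True
    swapped = oc.build_strategy_valuations(cfg)
    assert swapped["combo"].one_time_cost == pytest.approx(
        plain["mono"].one_time_cost)
    assert swapped["mono"].one_time_qaly_loss == pytest.approx(
        plain["combo"].one_time_qaly_loss)


def _bare_valuation(**overrides):
    base = dict(strategy="x", induction_cycles=4, first_line_induction=0.0,
                first_line_maintenance=0.0, background_per_cycle=0.0,
                pfs2_treatment=0.0, pd_per_cycle=0.0, one_time_cost=0.0,
                one_time_qaly_loss=0.0, end_of_life=0.0,
                subsequent_disc_per_cycle=0.0)
    base.update(overrides)
    return StrategyValuation(**base)


def _stationary_trace(n):
    return oc.run_trace(None, None, n, matrices=np.stack([np.eye(4)] * n))


def test_undiscounted_qaly_closed_form():
    """Cohort pinned in PFS at utility 0.71 for 348 cycles and no
    discounting accrues 0.71 * 348 * 21/365.25 = 14.206 QALYs."""
    trace = _stationary_trace(348)
    out = oc.accumulate(
        trace, _bare_valuation(),
        oc.EconomicSettings(annual_discount=0.0), oc.UtilitySet(pfs=0.71))
    assert out.qaly == pytest.approx(0.71 * 348 * 21 / 365.25, rel=1e-12)
    assert out.cost == 0.0


def test_end_of_life_cost_discounted_at_death_cycle():
    """A death mass one year in is valued at 1/1.03 of the terminal cost."""
    k = round(365.25 / 21)  # ~17.4 -> 17 cycles = 357 days
    n = 30
    mats = np.stack([np.eye(4)] * n)
    death = np.zeros((4, 4))
    death[0, 3] = 1.0
    death[1, 1] = death[2, 2] = death[3, 3] = 1.0
    mats[k - 1] = death
    trace = oc.run_trace(None, None, n, matrices=mats)
    out = oc.accumulate(trace, _bare_valuation(end_of_life=100.0),
                        oc.EconomicSettings(annual_discount=0.03),
                        oc.UtilitySet())
    expected = 100.0 * 1.03 ** (-k * 21 / 365.25)
    assert out.cost == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(100 / 1.03, rel=2e-3)


def test_cost_scales_linearly_with_unit_costs(base_pipeline):
    cfg = copy.deepcopy(base_pipeline.config)

    def scale(node, factor):
        for key, val in node.items():
            if isinstance(val, dict):
                scale(val, factor)
            elif isinstance(val, (int, float)) and key != "swap_arms":
                node[key] = val * factor

    trace = base_pipeline.traces["mono"]
    settings = oc.EconomicSettings()
    utils = oc.UtilitySet(disutilities=cfg["disutilities"], **cfg["utilities"])
    base = oc.accumulate(trace, oc.build_strategy_valuations(cfg)["mono"],
                         settings, utils)
    scale(cfg["costs"], 2.0)
    doubled = oc.accumulate(trace, oc.build_strategy_valuations(cfg)["mono"],
                            settings, utils)
    assert doubled.cost == pytest.approx(2 * base.cost, rel=1e-12)
    assert doubled.qaly == pytest.approx(base.qaly, rel=1e-12)


def test_discounting_orders_totals(base_pipeline):
    cfg = base_pipeline.config
    trace = base_pipeline.traces["mono"]
    vals = oc.build_strategy_valuations(cfg)["mono"]
    utils = oc.UtilitySet(disutilities=cfg["disutilities"], **cfg["utilities"])
    totals = [
        oc.accumulate(trace, vals, oc.EconomicSettings(annual_discount=r),
                      utils)
        for r in (0.0, 0.03, 0.08)
    ]
    assert totals[0].cost > totals[1].cost > totals[2].cost
    assert totals[0].qaly > totals[1].qaly > totals[2].qaly


def test_totals_monotone_in_horizon(base_pipeline):
    out = base_pipeline.outcomes["combo"]
    c10, q10 = out.by_horizon[10.0]
    c20, q20 = out.by_horizon[20.0]
    assert 0 < c10 <= c20 == pytest.approx(out.cost)
    assert 0 < q10 <= q20 == pytest.approx(out.qaly)


def test_unit_utility_reproduces_discounted_life_expectancy(consistent_funcs):
    """With all utilities 1 and no background mortality, total QALY equals
    discounted life expectancy computed directly from the generating OS."""
    nm = oc.NaturalMortality(annual_probability=0.0)
    trace = oc.run_trace(consistent_funcs, nm, 348, pd_denominator="lag")
    settings = oc.EconomicSettings(annual_discount=0.03)
    out = oc.accumulate(trace, _bare_valuation(),
                        settings, oc.UtilitySet(pfs=1.0, pfs2=1.0, pd=1.0))
    cycle_years = 21 / 365.25
    t = np.arange(348)
    df = 1.03 ** (-t * cycle_years)
    oracle = float(np.sum(consistent_funcs.S(t * CYCLE_MONTHS) * df
                          * cycle_years))
    assert out.qaly == pytest.approx(oracle, rel=0.02)
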