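"""Costs and QALYs from a Markov trace.

Converts per-cycle state occupancy into discounted US-dollar costs and
quality-adjusted life-years for each treatment strategy.  Cost components:

* PFS — first-line drug acquisition (induction agents for the first four
  cycles, maintenance thereafter), each agent's cost scaled by one minus its
  discontinuation proportion; infusion administration fees; per-cycle shares
  of monthly follow-up and trimonthly imaging.
* PFS-2 — a market-share basket of second-line regimens applied to the
  fraction of occupants still on second-line treatment (new progressors
  enter on treatment; the on-treatment fraction decays by the per-cycle
  discontinuation probability), plus follow-up/imaging shares.
* PD — best supportive care per cycle.
* One-time — EGFR mutation testing and expected SAE management cost at
  model entry (with matching one-time QALY decrements for SAE disutility),
  and an end-of-life care bundle per incident death.

Discounting applies a continuous-per-cycle factor (1+r)^(-t * 21/365.25) to
both costs and health outcomes, with state membership valued at cycle start
(no half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov_engine import CYCLE_DAYS, CYCLE_MONTHS, CYCLE_YEARS, MarkovTrace

__all__ = [
    "PatientProfile",
    "UtilitySet",
    "EconomicSettings",
    "StrategyValuation",
    "StrategyOutcome",
    "drug_dose_mg",
    "build_strategy_valuations",
    "accumulate",
]

DAYS_PER_MONTH = 30.4375


@dataclass
class PatientProfile:
    weight: float = 70.0   # kg
    bsa: float = 1.86      # m^2
    ccr: float = 70.0      # mL/min
    age: float = 65.0      # years

    def __post_init__(self):
        if min(self.weight, self.bsa, self.ccr, self.age) <= 0:
            raise ValueError("profile values must be positive")


@dataclass
class UtilitySet:
    pfs: float = 0.71
    pfs2: float = 0.74
    pd: float = 0.58
    death: float = 0.0
    disutilities: dict = field(default_factory=dict)  # SAE name -> disutility

    def __post_init__(self):
        for v in (self.pfs, self.pfs2, self.pd, self.death,
                  *self.disutilities.values()):
            if not 0.0 <= v <= 1.0:
                raise ValueError("utilities and disutilities must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array([self.pfs, self.pfs2, self.pd, self.death])


@dataclass
class EconomicSettings:
    wtp: float = 150_000.0
    annual_discount: float = 0.03
    cycle_days: float = CYCLE_DAYS
    horizon_years: float = 20.0

    def __post_init__(self):
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")
        if not 0.0 <= self.annual_discount <= 0.08:
            raise ValueError("annual_discount must lie in [0, 0.08]")


def drug_dose_mg(rule: str, amount: float, profile: PatientProfile) -> float:
    """Dose in mg implied by a dosing rule.

    ``flat_daily`` returns mg/day; ``per_m2``, ``per_kg``, ``flat`` return mg
    per administration; ``calvert`` returns AUC * (GFR + 25) with GFR
    approximated by creatinine clearance.
    """
    if rule == "flat_daily":
        return amount
    if rule == "flat":
        return amount
    if rule == "per_m2":
        return amount * profile.bsa
    if rule == "per_kg":
        return amount * profile.weight
    if rule == "calvert":
        return amount * (profile.ccr + 25.0)
    raise ValueError(f"unknown dosing rule {rule!r}")


def _check_non_negative(mapping: dict, label: str) -> None:
    for k, v in mapping.items():
        if isinstance(v, dict):
            _check_non_negative(v, f"{label}.{k}")
        elif isinstance(v, (int, float)) and v < 0:
            raise ValueError(f"negative cost input {label}.{k} = {v}")


@dataclass
class StrategyValuation:
    """Per-cycle and one-time cost components for one strategy."""

    strategy: str
    induction_cycles: int
    first_line_induction: float    # $ per person-cycle in PFS, cycles 0..3
    first_line_maintenance: float  # $ per person-cycle in PFS thereafter
    background_per_cycle: float    # follow-up + imaging share (PFS and PFS-2)
    pfs2_treatment: float          # $ per on-treatment person-cycle in PFS-2
    pd_per_cycle: float            # best supportive care
    one_time_cost: float           # EGFR testing + expected SAE management
    one_time_qaly_loss: float      # expected SAE disutility, one cycle long
    end_of_life: float             # $ per incident death
    subsequent_disc_per_cycle: float

    def pfs_cost(self, t: int) -> float:
        drug = (self.first_line_induction if t < self.induction_cycles
                else self.first_line_maintenance)
        return drug + self.background_per_cycle

    def cycle_cost(self, state: str, t: int,
                   on_treatment_fraction: float = 1.0) -> float:
        """Undiscounted $ per person-cycle for occupants of ``state`` at
        cycle t (one-time and end-of-life items are handled separately)."""
        if state == "pfs":
            return self.pfs_cost(t)
        if state == "pfs2":
            return (self.background_per_cycle
                    + on_treatment_fraction * self.pfs2_treatment)
        if state == "pd":
            return self.pd_per_cycle
        if state == "death":
            return 0.0
        raise ValueError(f"unknown state {state!r}")


def build_strategy_valuations(cfg: dict) -> dict[str, StrategyValuation]:
    """Price both strategies from a configuration dict (see config module)."""
    _check_non_negative(cfg["costs"], "costs")
    profile = PatientProfile(**cfg["profile"])
    prices = cfg["costs"]["drugs_per_mg"]
    admin = cfg["costs"]["administration"]
    reg = cfg["regimen"]
    disc = cfg["clinical"]["discontinuation"]

    cycle_days = cfg["economics"].get("cycle_days", CYCLE_DAYS)
    followup = cfg["costs"]["followup_per_month"] * cycle_days / DAYS_PER_MONTH
    imaging = cfg["costs"]["imaging_per_3_months"] * cycle_days / (3 * DAYS_PER_MONTH)
    background = followup + imaging

    osi_cycle = drug_dose_mg("flat_daily", reg["osimertinib_mg_per_day"],
                             profile) * cycle_days * prices["osimertinib"]
    pem_dose = drug_dose_mg("per_m2", reg["pemetrexed_mg_per_m2"], profile)
    pem_cycle = pem_dose * prices["pemetrexed"]
    if reg["platinum_agent"] == "carboplatin":
        plat_dose = drug_dose_mg("calvert", reg["carboplatin_auc"], profile)
        plat_cycle = plat_dose * prices["carboplatin"]
    elif reg["platinum_agent"] == "cisplatin":
        plat_dose = drug_dose_mg("per_m2", reg["cisplatin_mg_per_m2"], profile)
        plat_cycle = plat_dose * prices["cisplatin"]
    else:
        raise ValueError(f"unknown platinum agent {reg['platinum_agent']!r}")

    def infusion(hours: int) -> float:
        if hours <= 0:
            return 0.0
        return admin["first_hour"] + (hours - 1) * admin["additional_hour"]

    d_combo = disc["combo"]
    combo_induction = (
        osi_cycle * (1 - d_combo["osimertinib"])
        + pem_cycle * (1 - d_combo["pemetrexed"])
        + plat_cycle * (1 - d_combo["platinum"])
        + infusion(reg["infusion_hours_induction"])
    )
    combo_maintenance = (
        osi_cycle * (1 - d_combo["osimertinib"])
        + pem_cycle * (1 - d_combo["pemetrexed"])
        + infusion(reg["infusion_hours_maintenance"])
    )
    mono_cycle = osi_cycle * (1 - disc["mono"]["osimertinib"])

    sub = cfg["subsequent"]
    basket = {
        "platinum_pemetrexed": pem_cycle + plat_cycle + infusion(2),
        "first_gen_tki": 0.5 * (
            drug_dose_mg("flat_daily", sub["gefitinib_mg_per_day"], profile)
            * cycle_days * prices["gefitinib"]
        ) + 0.5 * (
            drug_dose_mg("flat_daily", sub["afatinib_mg_per_day"], profile)
            * cycle_days * prices["afatinib"]
        ),
        "bevacizumab_regimen": (
            drug_dose_mg("per_kg", sub["bevacizumab_mg_per_kg"], profile)
            * prices["bevacizumab"]
            + drug_dose_mg("per_m2", sub["nab_paclitaxel_mg_per_m2"], profile)
            * prices["nab_paclitaxel"]
            + plat_cycle
            + infusion(3)
        ),
        "pembrolizumab": (
            drug_dose_mg("flat", sub["pembrolizumab_mg_flat"], profile)
            * prices["pembrolizumab"]
            + infusion(1)
        ),
    }
    shares = sub["shares"]
    pfs2_treatment = sum(shares[k] * basket[k] for k in basket)

    risks = cfg["sae_risks"]
    arms = {"combo": "combo", "mono": "mono"}
    if risks.get("swap_arms", False):
        arms = {"combo": "mono", "mono": "combo"}
    sae_costs = cfg["costs"]["sae"]
    disutil = cfg["disutilities"]

    out = {}
    for strategy in ("combo", "mono"):
        r = risks[arms[strategy]]
        sae_cost = sum(r[k] * sae_costs[k] for k in r)
        sae_qaly = sum(r[k] * disutil[k] for k in r) * cycle_days / 365.25
        out[strategy] = StrategyValuation(
            strategy=strategy,
            induction_cycles=int(reg["induction_cycles"]),
            first_line_induction=(combo_induction if strategy == "combo"
                                  else mono_cycle),
            first_line_maintenance=(combo_maintenance if strategy == "combo"
                                    else mono_cycle),
            background_per_cycle=background,
            pfs2_treatment=pfs2_treatment,
            pd_per_cycle=cfg["costs"]["bsc_per_cycle"],
            one_time_cost=cfg["costs"]["egfr_testing"] + sae_cost,
            one_time_qaly_loss=sae_qaly,
            end_of_life=cfg["costs"]["end_of_life"],
            subsequent_disc_per_cycle=disc["subsequent_per_cycle"],
        )
    return out


@dataclass
class StrategyOutcome:
    strategy: str
    cost: float
    qaly: float
    by_horizon: dict = field(default_factory=dict)  # years -> (cost, qaly)


def _on_treatment_occupancy(trace: MarkovTrace, disc_per_cycle: float) -> np.ndarray:
    """Occupancy-scale fraction of the cohort in PFS-2 and still on
    second-line treatment at each cycle start."""
    n = trace.n_cycles
    on_tx = np.zeros(n + 1)
    for t in range(1, n + 1):
        retain = trace.matrices[t - 1][1, 1] if trace.matrices is not None else 1.0
        on_tx[t] = (on_tx[t - 1] * (1.0 - disc_per_cycle) * retain
                    + trace.incident_progressions[t])
    return on_tx


def accumulate(trace: MarkovTrace, valuation: StrategyValuation,
               settings: EconomicSettings, utilities: UtilitySet,
               report_horizons_years=None) -> StrategyOutcome:
    """Total discounted cost and QALY for one strategy over the trace."""
    n = trace.n_cycles
    cycle_years = settings.cycle_days / 365.25
    t_idx = np.arange(n + 1)
    df = (1.0 + settings.annual_discount) ** (-t_idx * cycle_years)

    u = utilities.as_vector()
    qaly_per_cycle = trace.occupancy[:n] @ u * cycle_years * df[:n]

    on_tx = _on_treatment_occupancy(trace, valuation.subsequent_disc_per_cycle)
    cost_per_cycle = np.empty(n)
    for t in range(n):
        occ = trace.occupancy[t]
        frac = on_tx[t] / occ[1] if occ[1] > 1e-15 else 0.0
        cost_per_cycle[t] = (
            occ[0] * valuation.cycle_cost("pfs", t)
            + occ[1] * valuation.cycle_cost("pfs2", t, on_treatment_fraction=frac)
            + occ[2] * valuation.cycle_cost("pd", t)
        ) * df[t]
    eol_per_cycle = trace.incident_deaths * valuation.end_of_life * df

    cost_cum = np.concatenate([[valuation.one_time_cost],
                               cost_per_cycle]).cumsum() + eol_per_cycle.cumsum()
    qaly_cum = np.concatenate([[-valuation.one_time_qaly_loss],
                               qaly_per_cycle]).cumsum()

    by_horizon = {}
    for years in report_horizons_years or []:
        k = min(int(round(years * 365.25 / settings.cycle_days)), n)
        by_horizon[float(years)] = (float(cost_cum[k]), float(qaly_cum[k]))

    return StrategyOutcome(
        strategy=valuation.strategy,
        cost=float(cost_cum[-1]),
        qaly=float(qaly_cum[-1]),
        by_horizon=by_horizon,
    )
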