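"""Model configuration: the structured parameter table and helpers.

``default_config()`` returns the base-case inputs for the comparison of
first-line osimertinib plus platinum-pemetrexed ("combo") versus osimertinib
monotherapy ("mono") from a US health-system perspective: 2023 US$ unit
costs, health-state utilities, serious-adverse-event (SAE) burden,
treatment-discontinuation proportions, the OS hazard ratio, and the
reference patient profile.  Configs are plain nested dicts, round-trippable
through YAML, with dot-path access for sensitivity-analysis overrides.

Note: the two arms' SAE risk vectors are carried exactly as sourced; the
``sae_risks.swap_arms`` flag exchanges them if the user judges the source
labels to be transposed.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

__all__ = ["default_config", "load_config", "save_config", "get_path", "set_path"]


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT)


_DEFAULT: dict[str, Any] = {
    "profile": {"weight": 70.0, "bsa": 1.86, "ccr": 70.0, "age": 65.0},
    "economics": {
        "wtp": 150_000.0,
        "annual_discount": 0.03,
        "cycle_days": 21.0,
        "horizon_years": 20.0,
        "report_horizons_years": [10.0, 20.0],
    },
    "mortality": {"mode": "constant", "annual_probability": 0.0197},
    "clinical": {
        "hr_os": {"point": 0.75, "low": 0.57, "high": 0.97},
        "discontinuation": {
            "combo": {"osimertinib": 0.4420, "platinum": 0.2319,
                      "pemetrexed": 0.7536},
            "mono": {"osimertinib": 0.5527},
            "subsequent_per_cycle": 0.03,
        },
    },
    "costs": {
        "drugs_per_mg": {
            "osimertinib": 7.08,
            "pemetrexed": 0.32,
            "cisplatin": 0.22,
            "carboplatin": 0.28,
            "nab_paclitaxel": 14.79,
            "gefitinib": 1.09,
            "afatinib": 9.76,
            "bevacizumab": 7.38,
            "pembrolizumab": 56.41,
        },
        "administration": {
            "first_hour": 132.16,
            "additional_hour": 28.47,
            "subsequent_per_hour": 65.06,
        },
        "imaging_per_3_months": 114.54,
        "bsc_per_cycle": 3006.28,
        "end_of_life": 40_708.33,
        "followup_per_month": 542.65,
        "egfr_testing": 1199.53,
        "sae": {"anemia": 2053.86, "neutropenia": 1295.15,
                "thrombocytopenia": 2252.54},
    },
    "utilities": {"pfs": 0.71, "pfs2": 0.74, "pd": 0.58, "death": 0.0},
    "disutilities": {"anemia": 0.07, "neutropenia": 0.46,
                     "thrombocytopenia": 0.25},
    "sae_risks": {
        "mono": {"anemia": 0.17, "neutropenia": 0.13, "thrombocytopenia": 0.07},
        "combo": {"anemia": 0.003, "neutropenia": 0.01, "thrombocytopenia": 0.0},
        "swap_arms": False,
    },
    "regimen": {
        # combo arm: osimertinib 80 mg daily throughout; pemetrexed
        # 500 mg/m2 q21d throughout; platinum (carboplatin AUC 5 or
        # cisplatin 75 mg/m2) during the 4 induction cycles only
        "platinum_agent": "carboplatin",
        "induction_cycles": 4,
        "osimertinib_mg_per_day": 80.0,
        "pemetrexed_mg_per_m2": 500.0,
        "cisplatin_mg_per_m2": 75.0,
        "carboplatin_auc": 5.0,
        # billed infusion hours: pemetrexed occupies the first hour,
        # the platinum agent one additional hour
        "infusion_hours_induction": 2,
        "infusion_hours_maintenance": 1,
    },
    "subsequent": {
        # second-line basket priced from the unit costs above; shares are an
        # assumption (equal by default)
        "shares": {
            "platinum_pemetrexed": 0.25,
            "first_gen_tki": 0.25,
            "bevacizumab_regimen": 0.25,
            "pembrolizumab": 0.25,
        },
        "gefitinib_mg_per_day": 250.0,
        "afatinib_mg_per_day": 40.0,
        "bevacizumab_mg_per_kg": 15.0,
        "nab_paclitaxel_mg_per_m2": 260.0,
        "pembrolizumab_mg_flat": 200.0,
    },
    # tail_ceiling: 20-year survival in advanced EGFR-mutant NSCLC is well
    # below 10%; fits plateauing above this at the horizon are rejected as
    # "tailing".  cross_tol absorbs sampling noise between independently
    # estimated endpoint curves; gross crossings (a PFS fit plateauing
    # above OS) exceed it by an order of magnitude.
    "selection": {"tail_ceiling": 0.10, "unified": True, "cross_tol": 0.06},
    "model": {"pd_denominator": "lead"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def get_path(cfg: dict, dotted: str):
    node = cfg
    for key in dotted.split("."):
        node = node[key]
    return node


def set_path(cfg: dict, dotted: str, value) -> dict:
    keys = dotted.split(".")
    node = cfg
    for key in keys[:-1]:
        node = node[key]
    if keys[-1] not in node:
        raise KeyError(f"unknown config path {dotted!r}")
    node[keys[-1]] = value
    return cfg
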