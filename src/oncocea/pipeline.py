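"""End-to-end orchestration: curves -> reconstruction -> fits -> trace -> CEA.

The pipeline consumes a config dict (see :mod:`oncocea.config`) plus one
digitized curve per endpoint/arm, reconstructs pseudo-IPD, fits the seven
candidate families, selects a family per endpoint (unified across arms by
default), derives the combination arm's OS from the monotherapy arm by the
proportional-hazards transform when running in ``substituted`` mode, runs
the Markov trace for both strategies and returns the comparative result.

A *synthetic* preset ships with the package: event times drawn from Weibull
ground truths whose progression-free survival medians approximate 29.4
versus 19.9 months and whose OS hazard ratio is 0.75, rendered as digitized
step curves with numbers-at-risk tables.  It is generated data for
demonstration and testing, not trial data.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import default_config, set_path
from .datatypes import ArmSpec, DigitizedCurve
from .economics import CEResult, compare, results_table
from .km_reconstruction import reconstruct_ipd
from .markov_engine import (CYCLE_MONTHS, NaturalMortality, horizon_cycles,
                            run_trace)
from .survival_models import (HazardRatio, SurvivalFunctionSet,
                              apply_hazard_ratio, fit_all, fit_table,
                              select_unified)
from .synthetic_data import render_km, simulate_ipd
from .valuation import (EconomicSettings, UtilitySet, accumulate,
                        build_strategy_valuations)

__all__ = [
    "ARMS",
    "preset_arm_specs",
    "preset_curves",
    "run_pipeline",
    "make_model_closure",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

ARMS = ("combo", "mono")
ENDPOINT_ORDER = ("OS", "PFS2", "PFS")

# synthetic preset medians (months): (combo, mono) per subgroup tag
_PRESET_PFS_MEDIANS = {
    "all": (29.4, 19.9),
    "L858R": (24.7, 13.9),
    "Ex19del": (27.9, 21.3),
    "CNSm": (24.9, 13.8),
    "noCNSm": (31.3, 27.0),
}
_PRESET = {
    "pfs_shape": 1.3,
    "pfs2_shape": 1.2,
    "pfs2_medians": (36.0, 30.0),
    "os_shape": 1.2,
    "os_median_mono": 38.6,
    "hr_os": 0.75,
    "n_patients": 279,
    "censor_rate": 0.005,
    "admin_censor": {"PFS": 45.0, "PFS2": 45.0, "OS": 62.0},
}


def _weibull_scale(median: float, shape: float) -> float:
    return median / np.log(2.0) ** (1.0 / shape)


def preset_arm_specs(subgroup: str = "all") -> dict[tuple[str, str], ArmSpec]:
    """Ground-truth arm specifications of the synthetic trial-like preset."""
    if subgroup not in _PRESET_PFS_MEDIANS:
        raise ValueError(f"unknown subgroup {subgroup!r}; "
                         f"choose from {sorted(_PRESET_PFS_MEDIANS)}")
    p = _PRESET
    med_pfs = dict(zip(ARMS, _PRESET_PFS_MEDIANS[subgroup]))
    med_pfs2 = dict(zip(ARMS, p["pfs2_medians"]))
    os_scale_mono = _weibull_scale(p["os_median_mono"], p["os_shape"])
    # Weibull PH identity: S^hr has scale lambda * hr**(-1/shape)
    os_scale_combo = os_scale_mono * p["hr_os"] ** (-1.0 / p["os_shape"])
    specs = {}
    for arm in ARMS:
        specs[("PFS", arm)] = ArmSpec(
            arm, "weibull",
            (p["pfs_shape"], _weibull_scale(med_pfs[arm], p["pfs_shape"])),
            p["n_patients"], p["censor_rate"], p["admin_censor"]["PFS"])
        specs[("PFS2", arm)] = ArmSpec(
            arm, "weibull",
            (p["pfs2_shape"], _weibull_scale(med_pfs2[arm], p["pfs2_shape"])),
            p["n_patients"], p["censor_rate"], p["admin_censor"]["PFS2"])
        scale = os_scale_mono if arm == "mono" else os_scale_combo
        specs[("OS", arm)] = ArmSpec(
            arm, "weibull", (p["os_shape"], scale),
            p["n_patients"], p["censor_rate"], p["admin_censor"]["OS"])
    return specs


def preset_curves(seed: int, subgroup: str = "all",
                  jitter_sd: float = 0.0) -> dict[tuple[str, str], DigitizedCurve]:
    """Render the synthetic preset as digitized curves with risk tables."""
    specs = preset_arm_specs(subgroup)
    curves = {}
    for i, ((endpoint, arm), spec) in enumerate(sorted(specs.items())):
        ipd = simulate_ipd(spec, seed=seed + 1000 * i, endpoint=endpoint)
        risk_times = np.arange(0.0, spec.admin_censor_time + 1e-9, 3.0)
        curves[(endpoint, arm)] = render_km(ipd, risk_times, jitter_sd=jitter_sd,
                                            seed=seed + 1000 * i + 1)
    return curves


class _GridFunction:
    """Survival values tabulated at cycle boundaries, evaluated by cycle
    index lookup (linear interpolation between boundaries)."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)

    def __call__(self, t_months):
        x = np.asarray(t_months, dtype=float) / CYCLE_MONTHS
        return np.interp(x, np.arange(len(self.values)), self.values)


@dataclass
class PipelineResult:
    config: dict
    selected: dict                      # endpoint -> distribution name
    fits: dict                          # (endpoint, arm) -> list[ParametricFit]
    funcs: dict                         # arm -> SurvivalFunctionSet
    traces: dict                        # arm -> MarkovTrace
    outcomes: dict                      # arm -> StrategyOutcome
    result: CEResult
    ipds: dict = field(default_factory=dict, repr=False)
    manifest: dict = field(default_factory=dict)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _select_families(cfg, fits, grid, os_funcs, pfs2_funcs):
    """Unified (or per-arm-identical) family selection per endpoint, walking
    OS -> PFS2 -> PFS so each stage can be filtered against its companion."""
    sel = cfg["selection"]
    ceiling, tol = sel["tail_ceiling"], sel.get("cross_tol", 0.01)
    selected = {}
    companions: dict[str, dict] = {}

    os_mode = cfg.get("run", {}).get("os_source", "substituted")
    os_arms = ("mono",) if os_mode == "substituted" else ARMS
    selected["OS"] = select_unified(
        {arm: fits[("OS", arm)] for arm in os_arms}, grid, ceiling)

    hr = cfg["clinical"]["hr_os"]["point"]
    for arm in os_arms:
        fit = next(f for f in fits[("OS", arm)]
                   if f.distribution == selected["OS"])
        os_funcs[arm] = _GridFunction(fit.sf(grid))
    for arm in ARMS:
        if arm not in os_arms:
            os_funcs[arm] = _GridFunction(
                apply_hazard_ratio(os_funcs["mono"], hr)(grid))

    selected["PFS2"] = select_unified(
        {arm: fits[("PFS2", arm)] for arm in ARMS}, grid, ceiling,
        companions={arm: {"upper": os_funcs[arm]} for arm in ARMS},
        cross_tol=tol)
    for arm in ARMS:
        fit = next(f for f in fits[("PFS2", arm)]
                   if f.distribution == selected["PFS2"])
        pfs2_funcs[arm] = _GridFunction(fit.sf(grid))

    selected["PFS"] = select_unified(
        {arm: fits[("PFS", arm)] for arm in ARMS}, grid, ceiling,
        companions={arm: {"upper": pfs2_funcs[arm]} for arm in ARMS},
        cross_tol=tol)
    return selected


def run_pipeline(cfg: dict | None = None,
                 curves: dict[tuple[str, str], DigitizedCurve] | None = None,
                 seed: int = 0, out_dir=None) -> PipelineResult:
    """Execute reconstruct -> fit -> select -> trace -> accumulate -> compare.

    ``curves`` maps (endpoint, arm) to digitized curves for endpoints PFS,
    PFS2 and both arms, plus OS for the mono arm (both arms when
    ``run.os_source`` is ``direct``).  When omitted, the synthetic preset is
    generated with ``seed``.
    """
    cfg = copy.deepcopy(cfg) if cfg is not None else default_config()
    run_cfg = cfg.setdefault("run", {})
    run_cfg.setdefault("os_source", "substituted")
    run_cfg.setdefault("subgroup", "all")
    if curves is None:
        curves = preset_curves(seed, subgroup=run_cfg["subgroup"])

    n_cycles = horizon_cycles(cfg["economics"]["horizon_years"])
    grid = np.arange(n_cycles + 1) * CYCLE_MONTHS

    ipds, fits = {}, {}
    needed = [("OS", "mono"), ("PFS2", "combo"), ("PFS2", "mono"),
              ("PFS", "combo"), ("PFS", "mono")]
    if run_cfg["os_source"] == "direct":
        needed.insert(0, ("OS", "combo"))
    for key in needed:
        if key not in curves:
            raise ValueError(f"missing curve for endpoint/arm {key}")
        ipds[key] = reconstruct_ipd(curves[key])
        fits[key] = fit_all(ipds[key])
        logger.info("fitted %s/%s: %d records, %d events",
                    key[0], key[1], len(ipds[key]), ipds[key].n_events)

    os_funcs: dict = {}
    pfs2_funcs: dict = {}
    selected = _select_families(cfg, fits, grid, os_funcs, pfs2_funcs)
    logger.info("selected distributions: %s", selected)

    # curve-consistency capping: enforce P <= P2 <= S pointwise so the
    # transition denominators stay non-negative (small tail crossings of
    # independently fitted curves would otherwise freeze the PD state)
    funcs = {}
    for arm in ARMS:
        pfs_fit = next(f for f in fits[("PFS", arm)]
                       if f.distribution == selected["PFS"])
        s_vals = os_funcs[arm].values
        p2_vals = np.minimum(pfs2_funcs[arm].values, s_vals)
        p_vals = np.minimum(pfs_fit.sf(grid), p2_vals)
        funcs[arm] = SurvivalFunctionSet(
            P=_GridFunction(p_vals), P2=_GridFunction(p2_vals),
            S=_GridFunction(s_vals), arm=arm)

    nm = NaturalMortality(
        mode=cfg["mortality"]["mode"],
        annual_probability=cfg["mortality"].get("annual_probability", 0.0197),
        life_table=cfg["mortality"].get("life_table"),
        baseline_age=cfg["profile"]["age"])
    pd_denom = cfg["model"]["pd_denominator"]

    traces = {arm: run_trace(funcs[arm], nm, n_cycles, pd_denom)
              for arm in ARMS}
    valuations = build_strategy_valuations(cfg)
    settings = EconomicSettings(
        wtp=cfg["economics"]["wtp"],
        annual_discount=cfg["economics"]["annual_discount"],
        cycle_days=cfg["economics"]["cycle_days"],
        horizon_years=cfg["economics"]["horizon_years"])
    utilities = UtilitySet(disutilities=cfg["disutilities"], **cfg["utilities"])
    outcomes = {
        arm: accumulate(traces[arm], valuations[arm], settings, utilities,
                        cfg["economics"].get("report_horizons_years"))
        for arm in ARMS
    }
    result = compare(outcomes["combo"], outcomes["mono"], settings.wtp)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "os_source": run_cfg["os_source"],
        "subgroup": run_cfg["subgroup"],
        "selected_distributions": selected,
        "n_cycles": n_cycles,
    }
    out = PipelineResult(config=cfg, selected=selected, fits=fits, funcs=funcs,
                         traces=traces, outcomes=outcomes, result=result,
                         ipds=ipds, manifest=manifest)
    if out_dir is not None:
        _write_artifacts(out, Path(out_dir))
    return out


def _write_artifacts(res: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (endpoint, arm), ipd in res.ipds.items():
        ipd.to_csv(out_dir / f"ipd_{endpoint}_{arm}.csv")
        fit_table(res.fits[(endpoint, arm)],
                  res.selected[endpoint]).to_csv(
            out_dir / f"fits_{endpoint}_{arm}.csv", index=False)
    for arm, trace in res.traces.items():
        trace.to_csv(out_dir / f"trace_{arm}.csv")
    results_table(res.result).to_csv(out_dir / "results.csv", index=False)
    summary = {
        "cost_combo": res.result.cost_a, "cost_mono": res.result.cost_b,
        "qaly_combo": res.result.qaly_a, "qaly_mono": res.result.qaly_b,
        "delta_cost": res.result.delta_cost, "delta_qaly": res.result.delta_qaly,
        "icer": res.result.icer, "inmb": res.result.inmb,
        "inhb": res.result.inhb,
        "by_horizon": {a: o.by_horizon for a, o in res.outcomes.items()},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(res.manifest, indent=2))


def make_model_closure(base: PipelineResult):
    """A fast re-evaluator over Table-1-style parameters for DSA/PSA.

    Survival-fit coefficients are held at their base-case estimates (curve
    uncertainty is outside the sensitivity scope); the OS hazard ratio,
    discount rate, patient profile, costs, utilities and proportions are
    re-read from the overridden config on every call.
    """
    base_cfg = base.config
    n_cycles = base.manifest["n_cycles"]
    pd_denom = base_cfg["model"]["pd_denominator"]
    substituted = base_cfg["run"]["os_source"] == "substituted"
    base_hr = base_cfg["clinical"]["hr_os"]["point"]
    mono_trace = base.traces["mono"]
    nm = NaturalMortality(
        mode=base_cfg["mortality"]["mode"],
        annual_probability=base_cfg["mortality"].get("annual_probability",
                                                     0.0197),
        life_table=base_cfg["mortality"].get("life_table"),
        baseline_age=base_cfg["profile"]["age"])
    base_mono_S = base.funcs["mono"].S.values

    def model(overrides: dict[str, float]) -> CEResult:
        cfg = copy.deepcopy(base_cfg)
        for path, value in overrides.items():
            set_path(cfg, path, float(value))
        hr = cfg["clinical"]["hr_os"]["point"]
        if substituted and hr != base_hr:
            s_vals = base_mono_S ** hr
            p2_vals = np.minimum(base.funcs["combo"].P2.values, s_vals)
            p_vals = np.minimum(base.funcs["combo"].P.values, p2_vals)
            combo_funcs = SurvivalFunctionSet(
                P=_GridFunction(p_vals), P2=_GridFunction(p2_vals),
                S=_GridFunction(s_vals), arm="combo")
            combo_trace = run_trace(combo_funcs, nm, n_cycles, pd_denom)
        else:
            combo_trace = base.traces["combo"]
        traces = {"combo": combo_trace, "mono": mono_trace}
        valuations = build_strategy_valuations(cfg)
        settings = EconomicSettings(
            wtp=cfg["economics"]["wtp"],
            annual_discount=cfg["economics"]["annual_discount"],
            cycle_days=cfg["economics"]["cycle_days"],
            horizon_years=cfg["economics"]["horizon_years"])
        utilities = UtilitySet(disutilities=cfg["disutilities"],
                               **cfg["utilities"])
        outcomes = {
            arm: accumulate(traces[arm], valuations[arm], settings, utilities)
            for arm in ARMS
        }
        return compare(outcomes["combo"], outcomes["mono"], settings.wtp)

    return model
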