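"""Deterministic (tornado) and probabilistic sensitivity analysis.

Both analyses drive a *model closure*: a callable taking a dict of
config-path overrides and returning a ``CEResult`` for the full pipeline
under those inputs.  The one-way analysis perturbs each parameter to its
bounds with everything else at baseline; the probabilistic analysis draws
all parameters jointly and independently from their assigned families
(costs gamma, proportions and utilities beta, body-surface area and
creatinine clearance normal, discount uniform, the OS hazard ratio
lognormal from its confidence interval), with standard deviations set to
10% of baseline where applicable, and summarises the replicates as a
cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import get_path
from .economics import CEResult

__all__ = [
    "ParameterDef",
    "TornadoEntry",
    "PSAResult",
    "dsa_bounds",
    "build_parameter_defs",
    "run_dsa",
    "tornado_table",
    "sample_parameters",
    "run_psa",
]

logger = logging.getLogger(__name__)

ROLES = ("cost", "proportion", "utility", "clinical_normal", "discount",
         "hazard_ratio")


@dataclass
class ParameterDef:
    """One model input eligible for sensitivity analysis.

    ``name`` is the dot-path of the value inside the config dict.  Explicit
    ``low``/``high`` bounds override the role-derived defaults.
    """

    name: str
    baseline: float
    role: str
    distribution: str = ""
    low: float | None = None
    high: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.distribution:
            self.distribution = {
                "cost": "gamma", "proportion": "beta", "utility": "beta",
                "clinical_normal": "normal", "discount": "uniform",
                "hazard_ratio": "lognormal",
            }[self.role]
        if not self.label:
            self.label = self.name
        lo, hi = dsa_bounds(self)
        if not lo <= self.baseline <= hi:
            raise ValueError(f"{self.name}: baseline outside [low, high]")


def dsa_bounds(p: ParameterDef) -> tuple[float, float]:
    """One-way bounds: costs/BSA/Ccr ±25%, proportions and utilities ±10%
    (capped at 1), discount rate [0, 0.08]; explicit bounds take priority."""
    if p.low is not None and p.high is not None:
        return (p.low, p.high)
    if p.role in ("cost", "clinical_normal"):
        return (p.baseline * 0.75, p.baseline * 1.25)
    if p.role in ("proportion", "utility"):
        return (p.baseline * 0.9, min(p.baseline * 1.1, 1.0))
    if p.role == "discount":
        return (0.0, 0.08)
    raise ValueError(f"no derived bounds for role {p.role!r}; supply explicit ones")


def build_parameter_defs(cfg: dict) -> list[ParameterDef]:
    """Enumerate every varied input of the base-case model from a config."""
    defs: list[ParameterDef] = []

    def add(path, role, **kw):
        defs.append(ParameterDef(path, float(get_path(cfg, path)), role, **kw))

    for drug in cfg["costs"]["drugs_per_mg"]:
        add(f"costs.drugs_per_mg.{drug}", "cost", label=f"cost of {drug} per mg")
    for item in cfg["costs"]["administration"]:
        add(f"costs.administration.{item}", "cost", label=f"infusion {item}")
    for path, lbl in [("costs.imaging_per_3_months", "trimonthly imaging"),
                      ("costs.bsc_per_cycle", "best supportive care"),
                      ("costs.end_of_life", "end-of-life care"),
                      ("costs.followup_per_month", "routine follow-up"),
                      ("costs.egfr_testing", "EGFR mutation testing")]:
        add(path, "cost", label=lbl)
    for sae in cfg["costs"]["sae"]:
        add(f"costs.sae.{sae}", "cost", label=f"{sae} management cost")

    add("profile.bsa", "clinical_normal", label="body surface area")
    add("profile.ccr", "clinical_normal", label="creatinine clearance")
    add("profile.weight", "clinical_normal", label="body weight")
    add("economics.annual_discount", "discount", label="discount rate")

    hr = cfg["clinical"]["hr_os"]
    defs.append(ParameterDef("clinical.hr_os.point", float(hr["point"]),
                             "hazard_ratio", low=float(hr["low"]),
                             high=float(hr["high"]), label="HR for OS"))

    for arm in ("combo", "mono"):
        for agent in cfg["clinical"]["discontinuation"][arm]:
            add(f"clinical.discontinuation.{arm}.{agent}", "proportion",
                label=f"{agent} discontinuation ({arm})")
    add("clinical.discontinuation.subsequent_per_cycle", "proportion",
        label="subsequent-treatment discontinuation per cycle")

    for state in ("pfs", "pfs2", "pd"):
        add(f"utilities.{state}", "utility", label=f"utility of {state.upper()}")
    for sae in cfg["disutilities"]:
        add(f"disutilities.{sae}", "utility", label=f"disutility of {sae}")
    for arm in ("mono", "combo"):
        for sae, risk in cfg["sae_risks"][arm].items():
            if risk > 0:
                add(f"sae_risks.{arm}.{sae}", "proportion",
                    label=f"risk of {sae} ({arm})")
    return defs


@dataclass
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float
    flagged: bool = False

    @property
    def spread(self) -> float:
        if np.isnan(self.icer_at_low) or np.isnan(self.icer_at_high):
            return np.nan
        return abs(self.icer_at_high - self.icer_at_low)


def run_dsa(model, params: list[ParameterDef]) -> list[TornadoEntry]:
    """One-way analysis: each parameter to its bounds, all else baseline.

    ``model`` maps {config path: value} overrides to a CEResult.  A model
    failure at a bound flags the entry rather than dropping it.
    """
    entries = []
    for p in params:
        lo, hi = dsa_bounds(p)
        icers, flagged = [], False
        for bound in (lo, hi):
            try:
                res = model({p.name: bound})
                icers.append(res.icer)
                if np.isnan(res.icer):
                    flagged = True
            except Exception as exc:  # noqa: BLE001 - flagged, never silent
                logger.warning("DSA failure for %s at %g: %s", p.name, bound, exc)
                icers.append(np.nan)
                flagged = True
        entries.append(TornadoEntry(p.label, icers[0], icers[1], flagged))
    entries.sort(key=lambda e: (np.isnan(e.spread), -(e.spread if not
                                np.isnan(e.spread) else 0.0)))
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter, "icer_low": e.icer_at_low,
         "icer_high": e.icer_at_high, "spread": e.spread, "flagged": e.flagged}
        for e in entries
    ])


def _beta_from_moments(m: float, sd: float):
    if not 0 < m < 1:
        return None
    v = sd * sd
    if v <= 0 or v >= m * (1 - m):
        return None
    k = m * (1 - m) / v - 1.0
    return m * k, (1 - m) * k


def sample_parameters(params: list[ParameterDef], rng: np.random.Generator,
                      sd_frac: float = 0.1) -> dict[str, float]:
    """One joint independent draw of all parameters.

    Standard deviations are ``sd_frac`` of baseline (the conventional 10%);
    ``sd_frac = 0`` degenerates every distribution to its baseline.  Beta
    parameters whose moments are infeasible fall back to a ±10% uniform.
    """
    draw = {}
    for p in params:
        m = p.baseline
        sd = sd_frac * abs(m)
        if sd_frac == 0.0 or (sd == 0.0 and p.role != "discount"):
            draw[p.name] = m
            continue
        if p.distribution == "gamma":
            shape = 1.0 / sd_frac**2
            draw[p.name] = rng.gamma(shape, m / shape)
        elif p.distribution == "beta":
            ab = _beta_from_moments(m, sd)
            if ab is None:
                logger.debug("beta moments infeasible for %s; ±10%% uniform",
                             p.name)
                lo, hi = max(0.9 * m, 0.0), min(1.1 * m, 1.0)
                draw[p.name] = rng.uniform(lo, hi)
            else:
                draw[p.name] = rng.beta(*ab)
        elif p.distribution == "normal":
            draw[p.name] = max(rng.normal(m, sd), 1e-9)
        elif p.distribution == "uniform":
            lo, hi = dsa_bounds(p)
            draw[p.name] = rng.uniform(lo, hi)
        elif p.distribution == "lognormal":
            if p.low is not None and p.high is not None:
                log_sd = (np.log(p.high) - np.log(p.low)) / 3.92
            else:
                log_sd = sd_frac
            draw[p.name] = rng.lognormal(np.log(m), log_sd)
        else:
            raise ValueError(f"unknown distribution {p.distribution!r}")
    return draw


@dataclass
class PSAResult:
    """Per-replicate strategy outcomes plus the acceptability curve."""

    cost_a: np.ndarray
    qaly_a: np.ndarray
    cost_b: np.ndarray
    qaly_b: np.ndarray
    n_failed: int = 0
    wtp_grid: np.ndarray | None = None

    @property
    def n_reps(self) -> int:
        return len(self.cost_a)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_a - self.cost_b

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_a - self.qaly_b

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        grid = np.asarray(wtp_grid if wtp_grid is not None else self.wtp_grid)
        prob = [(grid_v * self.delta_qaly - self.delta_cost > 0).mean()
                for grid_v in grid]
        return pd.DataFrame({"wtp": grid, "probability": prob})

    def probability_cost_effective(self, wtp: float) -> float:
        return float((wtp * self.delta_qaly - self.delta_cost > 0).mean())

    def samples_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rep": np.arange(self.n_reps),
            "cost_a": self.cost_a, "qaly_a": self.qaly_a,
            "cost_b": self.cost_b, "qaly_b": self.qaly_b,
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
        })


def run_psa(model, params: list[ParameterDef], n_reps: int = 1000,
            wtp_grid=None, seed: int = 0, sd_frac: float = 0.1) -> PSAResult:
    """Monte-Carlo PSA: ``n_reps`` full model evaluations under joint draws.

    Failed replicates are logged, excluded, and counted in ``n_failed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    for rep in range(n_reps):
        draw = sample_parameters(params, rng, sd_frac=sd_frac)
        try:
            res = model(draw)
            rows.append((res.cost_a, res.qaly_a, res.cost_b, res.qaly_b))
        except Exception as exc:  # noqa: BLE001 - counted, never silent
            logger.warning("PSA replicate %d failed: %s", rep, exc)
            n_failed += 1
    arr = np.asarray(rows, dtype=float).reshape(-1, 4)
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 300_000.0, 61)
    return PSAResult(cost_a=arr[:, 0], qaly_a=arr[:, 1], cost_b=arr[:, 2],
                     qaly_b=arr[:, 3], n_failed=n_failed,
                     wtp_grid=np.asarray(wtp_grid, dtype=float))
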