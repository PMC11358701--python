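"""Parametric fitting of pseudo-IPD and best-fit selection.

Each of the seven candidate families is fitted by right-censored maximum
likelihood, ``loglik = sum_events ln f(t) + sum_censored ln S(t)``, using a
multi-start quasi-Newton optimiser on an unconstrained reparameterization.
Model selection follows the lowest AIC subject to plausibility filters: the
selected curve must not cross above a companion curve it is nested under
(progression-free survival can never exceed overall survival) and must not
"tail" — extrapolate above a configurable survival ceiling at the model
horizon.  Ties are broken by BIC, then by parameter count.

The comparator arm's overall survival is derived from the reference arm by a
proportional-hazards transform, ``S'(t) = S(t)**HR``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import PseudoIPD
from .distributions import FAMILIES, get_family

__all__ = [
    "ParametricFit",
    "HazardRatio",
    "SurvivalFunctionSet",
    "fit_distribution",
    "fit_all",
    "select_best_fit",
    "select_unified",
    "apply_hazard_ratio",
    "fit_table",
]

logger = logging.getLogger(__name__)

_BIG = 1e12


@dataclass
class ParametricFit:
    """One fitted family with its information criteria."""

    distribution: str
    params: np.ndarray
    loglik: float
    n: int
    converged: bool = True
    se: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n) - 2 * self.loglik

    def sf(self, t):
        return get_family(self.distribution).sf(t, self.params)

    def survival_function(self) -> Callable:
        fam, p = get_family(self.distribution), self.params
        return lambda t: fam.sf(t, p)


@dataclass
class HazardRatio:
    point: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if self.point <= 0:
            raise ValueError("hazard ratio must be > 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (0 < self.ci_low <= self.point <= self.ci_high):
                raise ValueError("require 0 < ci_low <= point <= ci_high")


@dataclass
class SurvivalFunctionSet:
    """The three survival functions driving one arm's state transitions:
    P(t) progression-free, P2(t) second progression-free, S(t) overall."""

    P: Callable
    P2: Callable
    S: Callable
    arm: str = ""

    def at_times(self, t):
        t = np.asarray(t, dtype=float)
        return {"P": self.P(t), "P2": self.P2(t), "S": self.S(t)}


def _censored_negloglik(family, times, events):
    ev = events.astype(bool)
    t_event, t_cens = times[ev], times[~ev]

    def nll(x):
        params = family.from_unconstrained(x)
        with np.errstate(all="ignore"):
            ll = np.sum(family.logpdf(t_event, params))
            if len(t_cens):
                ll += np.sum(np.log(np.clip(family.sf(t_cens, params), 1e-300, None)))
        return _BIG if not np.isfinite(ll) else -ll

    return nll


def _hessian_se(family, params, times, events, rel_step=1e-4):
    """Standard errors from a central-difference Hessian in natural space."""
    k = len(params)

    def nll_nat(p):
        ev = events.astype(bool)
        with np.errstate(all="ignore"):
            ll = np.sum(family.logpdf(times[ev], p)) + np.sum(
                np.log(np.clip(family.sf(times[~ev], p), 1e-300, None))
            )
        return _BIG if not np.isfinite(ll) else -ll

    h = np.maximum(np.abs(params), 1e-3) * rel_step
    H = np.empty((k, k))
    f0 = nll_nat(params)
    for i in range(k):
        for j in range(i, k):
            pp = params.copy()
            if i == j:
                pp[i] += h[i]
                fp = nll_nat(pp)
                pp[i] -= 2 * h[i]
                fm = nll_nat(pp)
                H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    pp = params.copy()
                    pp[i] += si * h[i]
                    pp[j] += sj * h[j]
                    vals.append(nll_nat(pp))
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h[i] * h[j]
                )
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return None
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return None


def fit_distribution(ipd: PseudoIPD, distribution: str,
                     compute_se: bool = True) -> ParametricFit:
    """Fit one family to right-censored pseudo-IPD by maximum likelihood.

    Requires at least 10 records and one event.  A fit whose optimiser fails
    on every start is returned with ``converged=False`` and is excluded from
    selection.
    """
    family = get_family(distribution)
    times = np.clip(ipd.times, 1e-8, None)  # zero times break log-densities
    events = ipd.events
    if len(times) < 10:
        raise ValueError("need at least 10 records to fit")
    if events.sum() < 1:
        raise ValueError("need at least 1 event to fit")

    nll = _censored_negloglik(family, times, events)
    best = None
    for start in family.initial_values(times, events):
        x0 = family.to_unconstrained(np.asarray(start, dtype=float))
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-8,
                                         "fatol": 1e-10})
        res2 = optimize.minimize(nll, res.x, method="L-BFGS-B")
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
    converged = best is not None and best.fun < _BIG / 2
    if not converged:
        logger.warning("MLE did not converge for %s on %s/%s",
                       distribution, ipd.endpoint, ipd.arm)
        return ParametricFit(distribution, np.full(family.n_params, np.nan),
                             -np.inf, len(times), converged=False)
    params = family.from_unconstrained(best.x)
    se = _hessian_se(family, params, times, events) if compute_se else None
    return ParametricFit(distribution, params, -best.fun, len(times),
                         converged=True, se=se)


def fit_all(ipd: PseudoIPD, distributions: Sequence[str] | None = None,
            compute_se: bool = False) -> list[ParametricFit]:
    """Fit every candidate family; non-converged fits are kept but flagged."""
    out = []
    for name in distributions or sorted(FAMILIES):
        try:
            out.append(fit_distribution(ipd, name, compute_se=compute_se))
        except ValueError:
            raise
    return out


@dataclass
class SelectionError(Exception):
    violations: dict

    def __str__(self):
        lines = [f"  {k}: {v}" for k, v in self.violations.items()]
        return "no candidate fit passes the plausibility filters:\n" + "\n".join(lines)


def _check_fit(fit: ParametricFit, grid: np.ndarray, tail_ceiling: float,
               upper: Callable | None, lower: Callable | None,
               cross_tol: float) -> str | None:
    s = fit.sf(grid)
    if upper is not None and np.any(s > upper(grid) + cross_tol):
        return "crosses above companion curve on the horizon grid"
    if lower is not None and np.any(s < lower(grid) - cross_tol):
        return "crosses below companion curve on the horizon grid"
    if s[-1] > tail_ceiling:
        return (f"tail: survival {s[-1]:.3f} at horizon exceeds "
                f"ceiling {tail_ceiling}")
    return None


def select_best_fit(
    fits: Sequence[ParametricFit],
    grid: np.ndarray,
    tail_ceiling: float = 0.40,
    upper: Callable | None = None,
    lower: Callable | None = None,
    cross_tol: float = 0.005,
) -> ParametricFit:
    """Lowest-AIC converged fit passing the plausibility filters.

    Parameters
    ----------
    grid : evaluation times (months) spanning the model horizon; the last
        element is the horizon itself.
    tail_ceiling : maximum extrapolated survival allowed at the horizon.
    upper, lower : companion survival functions the candidate must stay
        below / above (e.g. OS above, PFS below), within ``cross_tol``.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError({"all": "no converged fits"})
    ranked = sorted(converged, key=lambda f: (f.aic, f.bic, f.n_params))
    violations = {}
    for fit in ranked:
        why = _check_fit(fit, grid, tail_ceiling, upper, lower, cross_tol)
        if why is None:
            return fit
        violations[fit.distribution] = why
    raise SelectionError(violations)


def select_unified(
    fits_by_arm: dict[str, Sequence[ParametricFit]],
    grid: np.ndarray,
    tail_ceiling: float = 0.40,
    companions: dict[str, dict] | None = None,
    cross_tol: float = 0.005,
) -> str:
    """Pick one family for an endpoint across all arms: the family with the
    lowest summed AIC whose fit passes the filters in every arm."""
    companions = companions or {}
    names = set.intersection(*(
        {f.distribution for f in fits if f.converged}
        for fits in fits_by_arm.values()
    ))
    scored = []
    violations = {}
    for name in names:
        ok, total_aic, total_bic = True, 0.0, 0.0
        for arm, fits in fits_by_arm.items():
            fit = next(f for f in fits if f.distribution == name)
            comp = companions.get(arm, {})
            why = _check_fit(fit, grid, tail_ceiling, comp.get("upper"),
                             comp.get("lower"), cross_tol)
            if why is not None:
                violations[f"{name}/{arm}"] = why
                ok = False
                break
            total_aic += fit.aic
            total_bic += fit.bic
        if ok:
            scored.append((total_aic, total_bic, name))
    if not scored:
        raise SelectionError(violations)
    return min(scored)[2]


def apply_hazard_ratio(base: Callable, hr: float) -> Callable:
    """Proportional-hazards transform of a survival function: t -> base(t)**hr."""
    if np.ndim(hr) != 0 or hr <= 0:
        raise ValueError("hazard ratio must be a positive scalar")
    return lambda t: np.asarray(base(t), dtype=float) ** hr


def fit_table(fits: Sequence[ParametricFit],
              selected: str | None = None) -> pd.DataFrame:
    """Summary table (distribution, params, loglik, AIC, BIC, selected)."""
    rows = []
    for f in fits:
        rows.append({
            "distribution": f.distribution,
            "params": " ".join(f"{p:.6g}" for p in np.atleast_1d(f.params)),
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "converged": f.converged,
            "selected": f.distribution == selected,
        })
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
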