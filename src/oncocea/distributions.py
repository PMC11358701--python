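"""Parametric survival-time families used for curve fitting and simulation.

Seven candidate families are supported: exponential, Weibull, log-logistic,
log-normal, gamma, generalized gamma and Gompertz.  Each family exposes the
survival function, log-density, random sampling and a set of data-driven
starting values for maximum-likelihood optimisation, with parameters mapped
to an unconstrained space so generic optimisers can be used.

Parameterizations (time unit: months):

============  ==========================  =========================================
family        parameters                  survival function S(t)
============  ==========================  =========================================
exponential   rate λ>0                    exp(-λ t)
weibull       shape k>0, scale λ>0        exp(-(t/λ)^k)
loglogistic   shape c>0, scale s>0        1 / (1 + (t/s)^c)
lognormal     mu∈R, sigma>0               1 - Φ((ln t - mu)/sigma)
gamma         shape a>0, scale s>0        1 - F_gamma(t/s; a)
gengamma      a>0, c>0, scale s>0         1 - F_gamma((t/s)^c; a)
gompertz      shape b∈R, rate λ>0         exp(-(λ/b)(e^{b t} - 1))
============  ==========================  =========================================

The Gompertz shape may be negative, in which case a fraction exp(λ/b) of the
population never experiences the event (a survival plateau); sampling returns
``inf`` for those subjects, which downstream code censors administratively.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["FAMILIES", "SurvivalFamily", "get_family"]

_TINY = 1e-300


def _safe_log(x):
    return np.log(np.clip(x, _TINY, None))


class SurvivalFamily:
    """Base class: a named parametric family of positive survival times."""

    name: str = ""
    param_names: tuple = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- natural <-> unconstrained parameter space -------------------------
    # Default: all parameters positive, optimised on the log scale.
    def to_unconstrained(self, params):
        return np.log(np.asarray(params, dtype=float))

    def from_unconstrained(self, x):
        return np.exp(np.asarray(x, dtype=float))

    # -- distribution interface --------------------------------------------
    def sf(self, t, params):
        raise NotImplementedError

    def logpdf(self, t, params):
        raise NotImplementedError

    def rvs(self, params, size, rng):
        raise NotImplementedError

    def initial_values(self, times, events):
        """Moment-style starting points for the MLE multi-start."""
        raise NotImplementedError

    def validate(self, params):
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"{self.name} expects {self.n_params} parameters, got {params.shape}"
            )
        return params


class Exponential(SurvivalFamily):
    name = "exponential"
    param_names = ("rate",)

    def sf(self, t, params):
        (rate,) = params
        return np.exp(-rate * np.asarray(t, dtype=float))

    def logpdf(self, t, params):
        (rate,) = params
        return np.log(rate) - rate * np.asarray(t, dtype=float)

    def rvs(self, params, size, rng):
        (rate,) = params
        return rng.exponential(1.0 / rate, size=size)

    def initial_values(self, times, events):
        total = max(np.sum(times), _TINY)
        rate = max(np.sum(events), 1.0) / total
        return [np.array([rate]), np.array([rate * 2.0]), np.array([rate / 2.0])]


class _ScipyFamily(SurvivalFamily):
    """Family backed by a scipy.stats distribution."""

    def _dist(self, params):
        raise NotImplementedError

    def sf(self, t, params):
        return self._dist(params).sf(np.asarray(t, dtype=float))

    def logpdf(self, t, params):
        return self._dist(params).logpdf(np.asarray(t, dtype=float))

    def rvs(self, params, size, rng):
        return self._dist(params).rvs(size=size, random_state=rng)


class Weibull(_ScipyFamily):
    name = "weibull"
    param_names = ("shape", "scale")

    def _dist(self, params):
        shape, scale = params
        return stats.weibull_min(shape, scale=scale)

    def initial_values(self, times, events):
        t_obs = times[events > 0] if np.any(events > 0) else times
        scale = max(np.mean(t_obs), 1e-3)
        return [np.array([1.0, scale]), np.array([1.5, scale]), np.array([0.7, scale])]


class LogLogistic(_ScipyFamily):
    name = "loglogistic"
    param_names = ("shape", "scale")

    def _dist(self, params):
        shape, scale = params
        return stats.fisk(shape, scale=scale)

    def initial_values(self, times, events):
        t_obs = times[events > 0] if np.any(events > 0) else times
        scale = max(np.median(t_obs), 1e-3)
        return [np.array([1.5, scale]), np.array([1.0, scale]), np.array([3.0, scale])]


class LogNormal(_ScipyFamily):
    name = "lognormal"
    param_names = ("mu", "sigma")

    def _dist(self, params):
        mu, sigma = params
        return stats.lognorm(sigma, scale=np.exp(mu))

    def to_unconstrained(self, params):
        mu, sigma = params
        return np.array([mu, np.log(sigma)])

    def from_unconstrained(self, x):
        return np.array([x[0], np.exp(x[1])])

    def initial_values(self, times, events):
        t_obs = times[events > 0] if np.any(events > 0) else times
        logs = np.log(np.clip(t_obs, 1e-6, None))
        mu, sigma = np.mean(logs), max(np.std(logs), 0.1)
        return [np.array([mu, sigma]), np.array([mu, sigma * 2.0])]


class Gamma(_ScipyFamily):
    name = "gamma"
    param_names = ("shape", "scale")

    def _dist(self, params):
        shape, scale = params
        return stats.gamma(shape, scale=scale)

    def initial_values(self, times, events):
        t_obs = times[events > 0] if np.any(events > 0) else times
        m, v = np.mean(t_obs), max(np.var(t_obs), 1e-6)
        shape = np.clip(m * m / v, 0.1, 50.0)
        scale = max(m / shape, 1e-3)
        return [np.array([shape, scale]), np.array([1.0, max(m, 1e-3)])]


class GenGamma(_ScipyFamily):
    name = "gengamma"
    param_names = ("a", "c", "scale")

    def _dist(self, params):
        a, c, scale = params
        return stats.gengamma(a, c, scale=scale)

    def initial_values(self, times, events):
        t_obs = times[events > 0] if np.any(events > 0) else times
        m = max(np.mean(t_obs), 1e-3)
        # gamma-like, weibull-like and a middle start
        return [
            np.array([1.0, 1.0, m]),
            np.array([2.0, 1.0, m / 2.0]),
            np.array([1.0, 1.5, m]),
            np.array([0.8, 0.8, m]),
        ]


class Gompertz(SurvivalFamily):
    """Gompertz: hazard h(t) = rate * exp(shape * t), shape of either sign."""

    name = "gompertz"
    param_names = ("shape", "rate")

    _B_EPS = 1e-9

    def to_unconstrained(self, params):
        shape, rate = params
        return np.array([shape, np.log(rate)])

    def from_unconstrained(self, x):
        return np.array([x[0], np.exp(x[1])])

    def _cumhaz(self, t, shape, rate):
        t = np.asarray(t, dtype=float)
        if abs(shape) < self._B_EPS:
            return rate * t
        return rate / shape * np.expm1(shape * t)

    def sf(self, t, params):
        shape, rate = params
        return np.exp(-self._cumhaz(t, shape, rate))

    def logpdf(self, t, params):
        shape, rate = params
        t = np.asarray(t, dtype=float)
        return np.log(rate) + shape * t - self._cumhaz(t, shape, rate)

    def rvs(self, params, size, rng):
        shape, rate = params
        u = rng.uniform(size=size)
        if abs(shape) < self._B_EPS:
            return -np.log(u) / rate
        arg = 1.0 - shape * np.log(u) / rate
        out = np.full(np.shape(u), np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / shape
        # shape < 0 leaves a plateau exp(rate/shape); those draws never fail
        return out

    def initial_values(self, times, events):
        total = max(np.sum(times), _TINY)
        rate = max(np.sum(events), 1.0) / total
        return [
            np.array([0.0, rate]),
            np.array([0.05, rate]),
            np.array([-0.05, rate]),
            np.array([0.1, rate / 2.0]),
        ]


FAMILIES: dict[str, SurvivalFamily] = {
    f.name: f
    for f in (
        Exponential(),
        Weibull(),
        LogLogistic(),
        LogNormal(),
        Gamma(),
        GenGamma(),
        Gompertz(),
    )
}


def get_family(name: str) -> SurvivalFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown distribution {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
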