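"""Trial-like survival data with known ground truth.

Simulates per-patient event times from a chosen parametric family, applies
exponential random censoring and an administrative follow-up cutoff, and
renders the result as the kind of artifact one would obtain by digitizing a
published Kaplan-Meier figure: step-curve coordinates plus a numbers-at-risk
table, optionally perturbed by digitization jitter.
"""

from __future__ import annotations

import numpy as np
from lifelines import KaplanMeierFitter

from .datatypes import ArmSpec, DigitizedCurve, PseudoIPD
from .distributions import get_family

__all__ = ["simulate_ipd", "render_km", "kaplan_meier_points"]


def simulate_ipd(spec: ArmSpec, seed: int, endpoint: str = "PFS") -> PseudoIPD:
    """Draw one arm of individual patient data.

    Each record's observed time is ``min(event time, random censor time,
    admin_censor_time)``; the event flag is 1 iff the event time is the
    smallest of the three.
    """
    rng = np.random.default_rng(seed)
    family = get_family(spec.distribution)
    event_times = family.rvs(np.asarray(spec.params, float), spec.n_patients, rng)
    if spec.censor_rate > 0:
        censor_times = rng.exponential(1.0 / spec.censor_rate, size=spec.n_patients)
    else:
        censor_times = np.full(spec.n_patients, np.inf)
    censor_times = np.minimum(censor_times, spec.admin_censor_time)
    observed = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return PseudoIPD(times=observed, events=events, arm=spec.label, endpoint=endpoint)


def kaplan_meier_points(ipd: PseudoIPD) -> np.ndarray:
    """Product-limit step points: (0, 1) then (t_i, S(t_i)) at each distinct
    event time."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    event_times = np.unique(ipd.times[ipd.events == 1])
    if len(event_times) == 0:
        return np.array([[0.0, 1.0]])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return np.vstack([[0.0, 1.0], np.column_stack([event_times, surv])])


def _monotone_decreasing_projection(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences
    (L2, uniform weights)."""
    # PAVA on -y for the non-decreasing problem
    vals = list(-np.asarray(y, dtype=float))
    blocks = [[v, 1] for v in vals]  # (mean, count)
    out: list[list[float]] = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            m2, c2 = out.pop()
            m1, c1 = out.pop()
            out.append([(m1 * c1 + m2 * c2) / (c1 + c2), c1 + c2])
    proj = np.concatenate([[m] * c for m, c in out])
    return -proj


def render_km(
    ipd: PseudoIPD,
    risk_times,
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> DigitizedCurve:
    """Render pseudo-IPD as a digitized-curve artifact.

    Parameters
    ----------
    risk_times : sorted times (months) at which numbers at risk are tabulated;
        must start at or before the first event.
    jitter_sd : standard deviation of additive Gaussian digitization noise on
        the probability scale; noisy values are truncated to [0, 1] and
        projected back onto non-increasing sequences.
    """
    risk_times = np.asarray(risk_times, dtype=float)
    if np.any(np.diff(risk_times) < 0):
        raise ValueError("risk_times must be sorted")
    coords = kaplan_meier_points(ipd)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = coords[1:, 1] + rng.normal(0.0, jitter_sd, size=len(coords) - 1)
        noisy = np.clip(noisy, 0.0, 1.0)
        coords = coords.copy()
        coords[1:, 1] = _monotone_decreasing_projection(
            np.minimum(noisy, 1.0)
        )
        coords[1:, 1] = np.minimum(coords[1:, 1], 1.0)
    # number at risk just before each tabulated time (all subjects at t=0)
    n_risk = np.array([(ipd.times >= t).sum() for t in risk_times], dtype=float)
    return DigitizedCurve(
        endpoint=ipd.endpoint,
        arm=ipd.arm,
        coords=coords,
        risk_table=np.column_stack([risk_times, n_risk]),
        total_events=ipd.n_events,
    )
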