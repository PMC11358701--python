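"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Implements the standard interval-wise reconstruction: the numbers-at-risk
table partitions follow-up into intervals; within each interval the survival
drops at the digitized coordinates are treated as event locations, and the
discrepancy between the coordinate-implied decrease in the risk set and the
observed change in numbers at risk is attributed to censoring, distributed
uniformly over the interval.  Fractional patient counts are resolved by
largest-remainder apportionment so that interval totals are preserved
exactly, and the reconstructed record count always equals the initial number
at risk.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import DigitizedCurve, PseudoIPD

__all__ = ["reconstruct_ipd"]

logger = logging.getLogger(__name__)


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` over ``fracs`` (non-negative weights)."""
    fracs = np.clip(np.asarray(fracs, dtype=float), 0.0, None)
    if total <= 0 or len(fracs) == 0:
        return np.zeros(len(fracs), dtype=int)
    if fracs.sum() <= 0:
        fracs = np.ones_like(fracs)
    scaled = fracs * total / fracs.sum()
    base = np.floor(scaled).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(scaled - base))
        base[order[:short]] += 1
    return base


def _interval_events(coord_t, coord_s, s_enter, n_enter, cens_times):
    """Sequential fractional event counts at each coordinate, interleaving the
    proposed censoring times."""
    d = np.zeros(len(coord_t))
    n_run = float(n_enter)
    s_prev = s_enter
    cens_times = np.sort(np.asarray(cens_times, dtype=float))
    ci = 0
    for k, (t_k, s_k) in enumerate(zip(coord_t, coord_s)):
        while ci < len(cens_times) and cens_times[ci] < t_k:
            n_run -= 1.0
            ci += 1
        if s_prev > 0 and n_run > 0:
            d[k] = max(n_run * (1.0 - s_k / s_prev), 0.0)
        n_run -= d[k]
        s_prev = s_k
    n_run -= len(cens_times) - ci
    return d, n_run


def reconstruct_ipd(
    curve: DigitizedCurve,
    calibrate_events: bool = False,
    max_iter: int = 50,
) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized curve and its risk table.

    Parameters
    ----------
    curve : digitized step-curve coordinates plus numbers at risk; the risk
        table needs at least two entries.
    calibrate_events : when True and ``curve.total_events`` is set, censored
        records are relabelled (latest first) so the reconstructed event
        count matches the reported total.  Off by default.

    Returns
    -------
    PseudoIPD with exactly ``curve.n_at_start`` records.
    """
    if len(curve.risk_table) < 2:
        raise ValueError("risk table needs at least two entries")
    coords = curve.coords
    T = curve.risk_table[:, 0]
    nrisk = np.round(curve.risk_table[:, 1]).astype(int)

    out_t: list[float] = []
    out_e: list[int] = []
    n_current = int(nrisk[0])

    for j in range(len(T)):
        t_lo = T[j]
        last_interval = j == len(T) - 1
        t_hi = np.inf if last_interval else T[j + 1]
        mask = (coords[:, 0] >= t_lo) & (coords[:, 0] < t_hi) & (coords[:, 0] > 0)
        coord_t = coords[mask, 0]
        coord_s = coords[mask, 1]
        s_enter = coords[coords[:, 0] < t_lo, 1][-1] if t_lo > 0 else 1.0

        if last_interval:
            d, n_run = _interval_events(coord_t, coord_s, s_enter, n_current, [])
            ev_total = min(int(round(d.sum())), n_current)
            ev_counts = _largest_remainder(d, ev_total)
            for t_k, cnt in zip(coord_t, ev_counts):
                out_t.extend([t_k] * cnt)
                out_e.extend([1] * cnt)
            leftover = n_current - ev_total
            t_end = max(coord_t[-1] if len(coord_t) else t_lo, t_lo)
            out_t.extend([t_end] * leftover)
            out_e.extend([0] * leftover)
            n_current = 0
            break

        total_leave = n_current - int(nrisk[j + 1])
        if total_leave < 0:
            logger.warning(
                "risk table increases at t=%.3g in %s/%s; clamped to 0 departures",
                t_hi, curve.endpoint, curve.arm,
            )
            total_leave = 0

        # iterate the interval censoring count to integer consistency
        width = t_hi - t_lo
        c_guess = 0
        d = np.zeros(len(coord_t))
        for _ in range(max_iter):
            cens = t_lo + (np.arange(c_guess) + 0.5) * width / max(c_guess, 1)
            d, n_end = _interval_events(coord_t, coord_s, s_enter, n_current, cens)
            diff = n_end - nrisk[j + 1]
            step = int(round(diff))
            if step == 0:
                break
            new_guess = c_guess + step
            if new_guess < 0:
                if c_guess == 0:
                    logger.warning(
                        "implied negative censoring in interval [%.3g, %.3g) of "
                        "%s/%s; censoring clamped at 0",
                        t_lo, t_hi, curve.endpoint, curve.arm,
                    )
                    break
                new_guess = 0
            if new_guess == c_guess:
                break
            c_guess = new_guess

        ev_total = min(int(round(d.sum())), total_leave)
        cens_total = total_leave - ev_total
        ev_counts = _largest_remainder(d, ev_total)
        for t_k, cnt in zip(coord_t, ev_counts):
            out_t.extend([t_k] * cnt)
            out_e.extend([1] * cnt)
        if cens_total > 0:
            cens = t_lo + (np.arange(cens_total) + 0.5) * width / cens_total
            out_t.extend(cens.tolist())
            out_e.extend([0] * cens_total)
        n_current = int(nrisk[j + 1])

    times = np.asarray(out_t)
    events = np.asarray(out_e, dtype=int)

    if calibrate_events and curve.total_events is not None:
        deficit = int(curve.total_events) - int(events.sum())
        if deficit != 0:
            flip_from = 0 if deficit > 0 else 1
            idx = np.nonzero(events == flip_from)[0]
            idx = idx[np.argsort(-times[idx])][: abs(deficit)]
            events[idx] = 1 - flip_from
            logger.info(
                "calibrated %d records toward reported event total %d",
                len(idx), curve.total_events,
            )

    order = np.argsort(times, kind="stable")
    return PseudoIPD(
        times=times[order], events=events[order],
        arm=curve.arm, endpoint=curve.endpoint,
    )
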