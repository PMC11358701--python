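"""Four-state Markov cohort engine on 21-day cycles.

States are {PFS, PFS-2, PD, Death}, Death absorbing, with the whole cohort
starting in PFS.  Per-cycle transition probabilities are derived from the
three fitted survival functions evaluated at cycle boundaries:

    P_PFS->PFS-2  = (P(t) - P(t+1)) / P(t)   - P_Natural
    P_PFS2->PD    = (P2(t) - P2(t+1)) / P2(t) - P_Natural
    P_PD->Death   = (S(t) - S(t+1)) / (S(t) - P2(t+1)) - P_Natural

with P_PFS->Death = P_PFS2->Death = P_Natural and diagonals as complements.
The PD->Death denominator is selectable between the "lead" form
S(t) - P2(t+1) (the default) and the "lag" form S(t) - P2(t).  Probabilities
falling outside [0, 1] are clipped, and rows are re-normalized through the
diagonal so each remains stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CYCLE_DAYS",
    "CYCLE_MONTHS",
    "CYCLE_YEARS",
    "STATES",
    "NaturalMortality",
    "MarkovTrace",
    "horizon_cycles",
    "natural_mortality_per_cycle",
    "build_transition_matrix",
    "run_trace",
]

CYCLE_DAYS = 21.0
CYCLE_MONTHS = 21.0 / 30.4375
CYCLE_YEARS = 21.0 / 365.25
STATES = ("pfs", "pfs2", "pd", "death")


def horizon_cycles(years: float) -> int:
    """Number of 21-day cycles in a horizon of the given length (20 y -> 348)."""
    return int(round(years * 365.25 / CYCLE_DAYS))


@dataclass
class NaturalMortality:
    """Background (non-disease) mortality, constant or age-indexed.

    ``annual_probability`` is used in constant mode.  In life-table mode,
    ``life_table`` maps age (years) to annual death probability; the age at
    cycle t is ``baseline_age + t * 21/365.25`` and ages beyond the table are
    carried forward from its last row.
    """

    mode: str = "constant"
    annual_probability: float = 0.0197
    life_table: np.ndarray | None = None  # (age, annual probability) rows
    baseline_age: float = 65.0

    def __post_init__(self):
        if self.mode not in ("constant", "life_table"):
            raise ValueError("mode must be 'constant' or 'life_table'")
        if self.mode == "life_table":
            if self.life_table is None:
                raise ValueError("life_table mode requires a table")
            self.life_table = np.atleast_2d(np.asarray(self.life_table, float))
        if not 0 <= self.annual_probability <= 1:
            raise ValueError("annual_probability must lie in [0, 1]")


def _annual_to_cycle(p_annual: float) -> float:
    return 1.0 - (1.0 - p_annual) ** (CYCLE_DAYS / 365.25)


def natural_mortality_per_cycle(nm: NaturalMortality, cycle: int = 0) -> float:
    """Per-cycle natural death probability at the given cycle index."""
    if nm.mode == "constant":
        return _annual_to_cycle(nm.annual_probability)
    age = nm.baseline_age + cycle * CYCLE_YEARS
    ages, probs = nm.life_table[:, 0], nm.life_table[:, 1]
    idx = np.searchsorted(ages, age, side="right") - 1
    idx = int(np.clip(idx, 0, len(ages) - 1))
    return _annual_to_cycle(float(probs[idx]))


def _drop_fraction(v_t: float, v_next: float) -> float:
    return (v_t - v_next) / v_t if v_t > 0 else 0.0


def _stochastic_row(off: dict[int, float], diag: int) -> np.ndarray:
    """Clip off-diagonal entries to [0,1], complement on the diagonal, and
    rescale off-diagonals if the complement is negative."""
    row = np.zeros(4)
    for j, p in off.items():
        row[j] = np.clip(p, 0.0, 1.0)
    total = row.sum()
    if total > 1.0:
        row /= total
        total = 1.0
    row[diag] = 1.0 - total
    return row


def build_transition_matrix(funcs, p_natural: float, t: int,
                            pd_denominator: str = "lead") -> np.ndarray:
    """4x4 row-stochastic matrix for cycle t.

    ``funcs`` is a SurvivalFunctionSet (or anything with P/P2/S callables
    taking time in months); ``p_natural`` is the per-cycle background
    mortality.
    """
    if pd_denominator not in ("lead", "lag"):
        raise ValueError("pd_denominator must be 'lead' or 'lag'")
    m_t, m_next = t * CYCLE_MONTHS, (t + 1) * CYCLE_MONTHS
    P_t, P_n = float(funcs.P(m_t)), float(funcs.P(m_next))
    P2_t, P2_n = float(funcs.P2(m_t)), float(funcs.P2(m_next))
    S_t, S_n = float(funcs.S(m_t)), float(funcs.S(m_next))

    p12 = _drop_fraction(P_t, P_n) - p_natural
    p23 = _drop_fraction(P2_t, P2_n) - p_natural
    denom = S_t - (P2_n if pd_denominator == "lead" else P2_t)
    p3d = (S_t - S_n) / denom - p_natural if denom > 0 else 0.0

    M = np.zeros((4, 4))
    M[0] = _stochastic_row({1: p12, 3: p_natural}, diag=0)
    M[1] = _stochastic_row({2: p23, 3: p_natural}, diag=1)
    M[2] = _stochastic_row({3: p3d}, diag=2)
    M[3, 3] = 1.0
    return M


@dataclass
class MarkovTrace:
    """Cohort occupancy over the horizon plus incident flows.

    ``occupancy[t]`` is the state distribution at the start of cycle t
    (t = 0..n_cycles); ``incident_deaths[t]`` / ``incident_progressions[t]``
    are the new deaths / new PFS-2 arrivals occurring at the transition into
    cycle t.
    """

    occupancy: np.ndarray
    incident_deaths: np.ndarray
    incident_progressions: np.ndarray
    matrices: np.ndarray = field(repr=False, default=None)

    @property
    def n_cycles(self) -> int:
        return len(self.occupancy) - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(df)))
        df["incident_deaths"] = self.incident_deaths
        df["incident_progressions"] = self.incident_progressions
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_trace(funcs, nm: NaturalMortality, n_cycles: int,
              pd_denominator: str = "lead",
              matrices: np.ndarray | None = None) -> MarkovTrace:
    """Run the cohort forward ``n_cycles`` cycles from (1, 0, 0, 0).

    ``matrices`` may supply precomputed per-cycle transition matrices
    (shape (n_cycles, 4, 4)), bypassing the survival functions.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    occ = np.zeros((n_cycles + 1, 4))
    occ[0, 0] = 1.0
    if matrices is None:
        matrices = np.stack([
            build_transition_matrix(
                funcs, natural_mortality_per_cycle(nm, t), t, pd_denominator
            )
            for t in range(n_cycles)
        ])
    inc_death = np.zeros(n_cycles + 1)
    inc_prog = np.zeros(n_cycles + 1)
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ matrices[t]
        inc_death[t + 1] = occ[t + 1, 3] - occ[t, 3]
        inc_prog[t + 1] = occ[t, 0] * matrices[t][0, 1]
    return MarkovTrace(occupancy=occ, incident_deaths=inc_death,
                       incident_progressions=inc_prog, matrices=matrices)
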