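"""Comparative cost-effectiveness outcomes.

Given two strategy outcomes (intervention a, comparator b) and a
willingness-to-pay threshold λ ($/QALY):

    ΔC   = C_a - C_b,  ΔE = E_a - E_b
    ICER = ΔC / ΔE                      (northeast/southwest quadrants only)
    INMB = λ·ΔE - ΔC                    (incremental net monetary benefit, $)
    INHB = ΔE - ΔC/λ                    (incremental net health benefit, QALY)

A strategy with ΔC < 0 and ΔE > 0 is *dominant*; with ΔC > 0 and ΔE < 0 it
is *dominated*; in either case (or when ΔE = 0) no ICER is reported,
because a signed ratio across quadrants is uninterpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .valuation import StrategyOutcome

__all__ = ["CEResult", "compare", "compare_values", "results_table"]


@dataclass
class CEResult:
    strategy_a: str
    strategy_b: str
    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_a - self.cost_b

    @property
    def delta_qaly(self) -> float:
        return self.qaly_a - self.qaly_b

    @property
    def dominance(self) -> str:
        """'dominant', 'dominated', or '' for the trade-off quadrants."""
        if self.delta_cost < 0 and self.delta_qaly > 0:
            return "dominant"
        if self.delta_cost > 0 and self.delta_qaly < 0:
            return "dominated"
        return ""

    @property
    def icer(self) -> float:
        """ΔC/ΔE, or NaN when undefined (ΔE = 0 or a dominance quadrant)."""
        if self.delta_qaly == 0 or self.dominance:
            return math.nan
        return self.delta_cost / self.delta_qaly

    @property
    def inmb(self) -> float:
        return self.wtp * self.delta_qaly - self.delta_cost

    @property
    def inhb(self) -> float:
        return self.delta_qaly - self.delta_cost / self.wtp

    @property
    def cost_effective(self) -> bool:
        return self.inmb > 0


def compare(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> CEResult:
    """Intervention ``a`` versus comparator ``b`` at the given threshold."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    return CEResult(
        strategy_a=a.strategy, strategy_b=b.strategy,
        cost_a=a.cost, cost_b=b.cost,
        qaly_a=a.qaly, qaly_b=b.qaly, wtp=wtp,
    )


def compare_values(cost_a, qaly_a, cost_b, qaly_b, wtp,
                   label_a="a", label_b="b") -> CEResult:
    """Compare from raw totals (convenience for tests and toy models)."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    return CEResult(label_a, label_b, cost_a, cost_b, qaly_a, qaly_b, wtp)


def results_table(res: CEResult) -> pd.DataFrame:
    """Two-row results layout: cost, incremental cost, QALY, incremental
    QALY, INMB, INHB, ICER."""
    icer = res.dominance if res.dominance else res.icer
    return pd.DataFrame([
        {"treatment": res.strategy_a, "cost": res.cost_a,
         "incremental_cost": res.delta_cost, "qaly": res.qaly_a,
         "incremental_qaly": res.delta_qaly, "inmb": res.inmb,
         "inhb": res.inhb, "icer": icer},
        {"treatment": res.strategy_b, "cost": res.cost_b,
         "incremental_cost": None, "qaly": res.qaly_b,
         "incremental_qaly": None, "inmb": None, "inhb": None, "icer": None},
    ])
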