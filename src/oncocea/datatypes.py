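"""Shared domain containers: simulated arms, digitized curves, pseudo-IPD.

These are the objects passed between the synthetic-data generator, the
Kaplan-Meier reconstruction stage and the parametric fitting stage.  All
times are in months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENDPOINTS = ("PFS", "PFS2", "OS")


@dataclass
class ArmSpec:
    """Ground-truth description of one simulated trial arm.

    Parameters
    ----------
    label : arm name, e.g. ``"combo"``.
    distribution : one of the seven supported family names.
    params : parameter vector in the family's natural parameterization
        (time unit months).
    n_patients : number of subjects.
    censor_rate : rate of an exponential random-censoring process
        (per month); 0 disables random censoring.
    admin_censor_time : administrative follow-up cutoff in months.
    """

    label: str
    distribution: str
    params: tuple
    n_patients: int
    censor_rate: float = 0.0
    admin_censor_time: float = 60.0

    def __post_init__(self):
        from .distributions import get_family

        get_family(self.distribution).validate(self.params)
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")


@dataclass
class PseudoIPD:
    """Individual patient records: (time, event) pairs for one arm/endpoint."""

    times: np.ndarray
    events: np.ndarray
    arm: str = ""
    endpoint: str = "PFS"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "event": self.events, "arm": self.arm}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, endpoint: str = "PFS") -> "PseudoIPD":
        df = pd.read_csv(path)
        arm = str(df["arm"].iloc[0]) if "arm" in df else ""
        return cls(
            times=df["time_months"].to_numpy(),
            events=df["event"].to_numpy(),
            arm=arm,
            endpoint=endpoint,
        )


@dataclass
class DigitizedCurve:
    """Step-curve coordinates plus a numbers-at-risk table for one endpoint/arm.

    ``coords`` is an (k, 2) array of (time months, survival probability) with
    a leading (0, 1.0) anchor; ``risk_table`` is an (m, 2) array of
    (time months, number at risk).
    """

    endpoint: str
    arm: str
    coords: np.ndarray
    risk_table: np.ndarray
    total_events: int | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.risk_table = np.atleast_2d(np.asarray(self.risk_table, dtype=float))
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        t, s = self.coords[:, 0], self.coords[:, 1]
        if not (t[0] == 0.0 and abs(s[0] - 1.0) < 1e-12):
            raise ValueError("first coordinate must be (0, 1.0)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("coordinate times must be strictly increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if np.any(np.diff(self.risk_table[:, 1]) > 0):
            raise ValueError("numbers at risk must be non-increasing")

    @property
    def n_at_start(self) -> int:
        return int(round(self.risk_table[0, 1]))

    def survival_at(self, t) -> np.ndarray:
        """Step-function (right-continuous) evaluation of the digitized curve."""
        idx = np.searchsorted(self.coords[:, 0], np.asarray(t, dtype=float), "right") - 1
        return self.coords[np.clip(idx, 0, len(self.coords) - 1), 1]

    def to_csv(self, curve_path, risk_path) -> None:
        pd.DataFrame(self.coords, columns=["time_months", "survival"]).to_csv(
            curve_path, index=False
        )
        pd.DataFrame(self.risk_table, columns=["time_months", "n_risk"]).to_csv(
            risk_path, index=False
        )

    @classmethod
    def from_csv(cls, curve_path, risk_path, endpoint="PFS", arm="",
                 total_events=None) -> "DigitizedCurve":
        coords = pd.read_csv(curve_path)[["time_months", "survival"]].to_numpy()
        risk = pd.read_csv(risk_path)[["time_months", "n_risk"]].to_numpy()
        return cls(endpoint=endpoint, arm=arm, coords=coords, risk_table=risk,
                   total_events=total_events)
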