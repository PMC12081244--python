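"""Partitioned-survival cohort trace over a 3-state model (PFS / PD / death).

State occupancy at each cycle boundary is read directly off the fitted
curves: progression-free = S_PFS(t), dead = 1 - S_OS(t), progressed = the
remainder.  Transitions are unidirectional; the cohort starts fully
progression-free.  Defaults follow the evaluated design: 21-day cycles, a
5-year horizon (87 cycles), 3% annual discounting applied per cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

__all__ = [
    "ModelSettings",
    "CohortTrace",
    "build_trace",
    "discount_factor",
    "life_years",
    "transition_probabilities",
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
]


@dataclass(frozen=True)
class ModelSettings:
    cycle_length_days: float = 21.0
    horizon_years: float = 5.0
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be > 0")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")

    @property
    def n_cycles(self) -> int:
        """Ceiling of horizon / cycle length (87 at defaults); the final
        cycle is counted in full."""
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass
class CohortTrace:
    """Occupancy at cycle boundaries 0..n_cycles (rows sum to 1)."""

    df: pd.DataFrame  # columns: cycle, time_months, pfs, pd, death, new_deaths

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        d = self.df
        sums = d[["pfs", "pd", "death"]].sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 1.0) > 1e-10):
            raise ValueError("trace rows must sum to 1 within 1e-10")
        if np.any(np.diff(d["death"].to_numpy()) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")
        if np.any(np.diff(d["pfs"].to_numpy()) > 1e-12):
            raise ValueError("PFS occupancy must be non-increasing")

    @property
    def pfs(self) -> np.ndarray:
        return self.df["pfs"].to_numpy()

    @property
    def pd_state(self) -> np.ndarray:
        return self.df["pd"].to_numpy()

    @property
    def death(self) -> np.ndarray:
        return self.df["death"].to_numpy()

    @property
    def new_deaths(self) -> np.ndarray:
        return self.df["new_deaths"].to_numpy()

    @property
    def n_cycles(self) -> int:
        return len(self.df) - 1


def build_trace(pfs_model, os_model, settings: ModelSettings) -> CohortTrace:
    """Evaluate both fitted curves at every cycle boundary.

    Any region where the fitted PFS curve crosses above the fitted OS curve
    (possible because endpoints are fitted independently) is clipped to zero
    progressed-disease occupancy and logged with the worst violation.
    """
    k = np.arange(settings.n_cycles + 1)
    t_months = k * settings.cycle_length_months
    s_pfs = np.asarray(pfs_model.survival_at(t_months), dtype=float)
    s_os = np.asarray(os_model.survival_at(t_months), dtype=float)
    violation = float(np.max(s_pfs - s_os, initial=0.0))
    if violation > 1e-12:
        logger.warning("PFS curve exceeds OS curve; max violation %.3e clipped to 0 PD", violation)
    pfs = np.minimum(s_pfs, s_os)
    death = 1.0 - s_os
    pd_frac = s_os - pfs
    new_deaths = np.diff(death, prepend=death[0])
    new_deaths[0] = death[0]
    df = pd.DataFrame(
        {
            "cycle": k,
            "time_months": t_months,
            "pfs": pfs,
            "pd": pd_frac,
            "death": death,
            "new_deaths": new_deaths,
        }
    )
    return CohortTrace(df)


def discount_factor(cycle_index, settings: ModelSettings) -> np.ndarray | float:
    """Per-cycle discount factor (1 + r)^(-t_years), t at the cycle boundary."""
    if settings.annual_discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    cycle_index = np.asarray(cycle_index, dtype=float)
    if np.any(cycle_index < 0):
        raise ValueError("cycle_index must be >= 0")
    years = cycle_index * settings.cycle_length_years
    out = (1.0 + settings.annual_discount_rate) ** (-years)
    return float(out) if out.ndim == 0 else out


def _cycle_occupancy(values: np.ndarray, settings: ModelSettings) -> np.ndarray:
    """Occupancy attributed to accrual cycles 0..n_cycles-1 (start-of-cycle,
    or adjacent-boundary average under half-cycle correction)."""
    if settings.half_cycle_correction:
        return 0.5 * (values[:-1] + values[1:])
    return values[:-1]


def life_years(trace: CohortTrace, settings: ModelSettings, discounted: bool = False) -> float:
    """Time alive over the horizon, in years (optionally discount-weighted)."""
    alive = trace.pfs + trace.pd_state
    occ = _cycle_occupancy(alive, settings)
    w = discount_factor(np.arange(len(occ)), settings) if discounted else 1.0
    return float(np.sum(occ * w) * settings.cycle_length_years)


def transition_probabilities(trace: CohortTrace) -> pd.DataFrame:
    """Implied per-cycle transition probabilities for a strict Markov reading.

    Deaths are attributed to the PD state first (progression precedes death
    in the unidirectional structure); any excess mortality beyond the PD pool
    is drawn from PFS.  Returned per accrual cycle: P(PFS->PFS), P(PFS->PD),
    P(PFS->death), P(PD->death).
    """
    pfs, pdz, death = trace.pfs, trace.pd_state, trace.death
    rows = []
    for k in range(trace.n_cycles):
        leave_pfs = pfs[k] - pfs[k + 1]
        d_death = death[k + 1] - death[k]
        deaths_from_pd = min(d_death, pdz[k])
        deaths_from_pfs = d_death - deaths_from_pd
        to_pd = max(leave_pfs - deaths_from_pfs, 0.0)
        p = lambda num, den: min(max(num / den, 0.0), 1.0) if den > 1e-15 else 0.0
        rows.append(
            {
                "cycle": k,
                "p_pfs_pfs": p(pfs[k + 1], pfs[k]),
                "p_pfs_pd": p(to_pd, pfs[k]),
                "p_pfs_death": p(deaths_from_pfs, pfs[k]),
                "p_pd_death": p(deaths_from_pd, pdz[k]),
            }
        )
    return pd.DataFrame(rows)
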