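"""Costing, QALY accounting and incremental cost-effectiveness statistics.

Costs (2023 USD) accrue against the cohort trace: drug acquisition and
progression-free monitoring while in PFS (treatment runs until progression),
supportive care while progressed, a one-off end-of-life cost on each death,
and incidence-weighted adverse-event management applied once at model entry.
Health outcomes are utility-weighted life years (PFS 0.71, PD 0.67 at base
case) minus one-off AE disutilities.  Everything is discounted per cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTrace, ModelSettings, discount_factor, life_years, _cycle_occupancy

__all__ = [
    "UtilitySet",
    "AdverseEvent",
    "StrategySpec",
    "EconomicOutcome",
    "CEComparison",
    "accumulate_costs",
    "accumulate_qalys",
    "evaluate_strategy",
    "compare",
    "frontier",
    "outcomes_table",
]


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities; death is fixed at 0.

    Base-case utilities are ordered (u_pd <= u_pfs) and config validation
    enforces that; sensitivity evaluations may legitimately invert the
    ordering because the published ranges overlap (PFS 0.57-0.85 vs PD
    0.47-0.71) and parameters vary one at a time or are drawn independently.
    Inversions are therefore warned about, not rejected.
    """

    pfs: float = 0.71
    pd: float = 0.67

    def __post_init__(self) -> None:
        if not (0.0 <= self.pd <= 1.0 and 0.0 <= self.pfs <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        if self.pd > self.pfs:
            warnings.warn(
                f"u_pd ({self.pd}) exceeds u_pfs ({self.pfs}); allowed in sensitivity runs",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"{self.name}: incidence must be in [0, 1]")
        if self.cost < 0 or not 0.0 <= self.disutility <= 1.0:
            raise ValueError(f"{self.name}: cost >= 0 and disutility in [0, 1] required")


@dataclass(frozen=True)
class StrategySpec:
    """Per-strategy cost structure, already resolved to per-cycle amounts.

    ``pfs_cycle_cost_items``/``pd_cycle_cost_items`` map item name to the
    effective per-cycle cost (unit cost amortized over its billing interval).
    """

    name: str
    drug_cost_per_cycle: float
    pfs_cycle_cost_items: Mapping[str, float] = field(default_factory=dict)
    pd_cycle_cost_items: Mapping[str, float] = field(default_factory=dict)
    end_of_life_cost: float = 0.0
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        costs = [self.drug_cost_per_cycle, self.end_of_life_cost]
        costs += list(self.pfs_cycle_cost_items.values()) + list(self.pd_cycle_cost_items.values())
        if any(c < 0 for c in costs):
            raise ValueError(f"{self.name}: all costs must be >= 0")


@dataclass
class EconomicOutcome:
    strategy: str
    drug_cost: float
    monitoring_cost: float
    ae_cost: float
    eol_cost: float
    life_years: float
    qalys: float

    @property
    def total_cost(self) -> float:
        return self.drug_cost + self.monitoring_cost + self.ae_cost + self.eol_cost


@dataclass
class CEComparison:
    """Pairwise incremental statistics of strategy a vs strategy b."""

    a: str
    b: str
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "undefined"
    nmb_difference: float
    wtp: float


def accumulate_costs(trace: CohortTrace, strategy: StrategySpec, settings: ModelSettings) -> dict[str, float]:
    """Discounted cost components for one strategy on one trace."""
    occ_pfs = _cycle_occupancy(trace.pfs, settings)
    occ_pd = _cycle_occupancy(trace.pd_state, settings)
    w = discount_factor(np.arange(len(occ_pfs)), settings)
    pfs_weight = float(np.sum(occ_pfs * w))
    pd_weight = float(np.sum(occ_pd * w))

    drug = strategy.drug_cost_per_cycle * pfs_weight
    monitoring = sum(strategy.pfs_cycle_cost_items.values()) * pfs_weight
    monitoring += sum(strategy.pd_cycle_cost_items.values()) * pd_weight

    cycles = np.arange(1, trace.n_cycles + 1)
    eol = strategy.end_of_life_cost * float(
        np.sum(trace.new_deaths[1:] * discount_factor(cycles, settings))
    )
    ae = sum(a.incidence * a.cost for a in strategy.ae_profile)
    return {"drug_cost": drug, "monitoring_cost": monitoring, "eol_cost": eol, "ae_cost": ae}


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    ae_profile: Sequence[AdverseEvent],
    settings: ModelSettings,
) -> float:
    """Discounted QALYs minus one-off incidence-weighted AE disutility."""
    occ_pfs = _cycle_occupancy(trace.pfs, settings)
    occ_pd = _cycle_occupancy(trace.pd_state, settings)
    w = discount_factor(np.arange(len(occ_pfs)), settings)
    q = settings.cycle_length_years * float(
        np.sum(w * (utilities.pfs * occ_pfs + utilities.pd * occ_pd))
    )
    q -= sum(a.incidence * a.disutility for a in ae_profile)
    return q


def evaluate_strategy(
    trace: CohortTrace, strategy: StrategySpec, utilities: UtilitySet, settings: ModelSettings
) -> EconomicOutcome:
    costs = accumulate_costs(trace, strategy, settings)
    return EconomicOutcome(
        strategy=strategy.name,
        life_years=life_years(trace, settings, discounted=True),
        qalys=accumulate_qalys(trace, utilities, strategy.ae_profile, settings),
        **costs,
    )


def compare(a: EconomicOutcome, b: EconomicOutcome, wtp: float) -> CEComparison:
    """Incremental cost, QALYs, ICER (or dominance label) and NMB of a vs b."""
    d_cost = a.total_cost - b.total_cost
    d_q = a.qalys - b.qalys
    nmb_diff = wtp * d_q - d_cost
    if d_q == 0:
        icer, label = None, "undefined"
    elif d_q > 0 and d_cost <= 0:
        icer, label = None, "dominant"
    elif d_q < 0 and d_cost >= 0:
        icer, label = None, "dominated"
    else:
        icer, label = d_cost / d_q, "icer"
    return CEComparison(
        a=a.strategy,
        b=b.strategy,
        incremental_cost=d_cost,
        incremental_qalys=d_q,
        icer=icer,
        label=label,
        nmb_difference=nmb_diff,
        wtp=wtp,
    )


def frontier(outcomes: Sequence[EconomicOutcome]) -> pd.DataFrame:
    """Cost-effectiveness frontier with strict and extended dominance flags.

    Strategies are sorted by cost; a strategy is dominated if another is no
    more costly and no less effective (strictly better on one axis), and
    extendedly dominated if dropping it lowers some pairwise ICER along the
    remaining frontier.  Exact ties in both cost and QALYs are retained and
    flagged.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier needs >= 2 strategies")
    df = pd.DataFrame(
        {
            "strategy": [o.strategy for o in outcomes],
            "cost": [o.total_cost for o in outcomes],
            "qalys": [o.qalys for o in outcomes],
        }
    ).sort_values(["cost", "qalys"], ascending=[True, False], ignore_index=True)
    status = ["frontier"] * len(df)
    for i in range(len(df)):
        for j in range(len(df)):
            if i == j:
                continue
            ci, qi = df.loc[i, "cost"], df.loc[i, "qalys"]
            cj, qj = df.loc[j, "cost"], df.loc[j, "qalys"]
            if cj <= ci and qj >= qi and (cj < ci or qj > qi):
                status[i] = "dominated"
                break
            if cj == ci and qj == qi and j < i:
                status[i] = "tie"
    # extended dominance: repeatedly drop strategies breaking ICER monotonicity
    changed = True
    while changed:
        changed = False
        idx = [i for i in range(len(df)) if status[i] in ("frontier", "tie")]
        for pos in range(1, len(idx) - 1):
            lo, mid, hi = idx[pos - 1], idx[pos], idx[pos + 1]
            icer_in = _icer(df, lo, mid)
            icer_out = _icer(df, mid, hi)
            if icer_in is not None and icer_out is not None and icer_in > icer_out:
                status[mid] = "extended_dominated"
                changed = True
                break
    icers: list[float | None] = [None] * len(df)
    front = [i for i in range(len(df)) if status[i] == "frontier"]
    for prev, curr in zip(front, front[1:]):
        icers[curr] = _icer(df, prev, curr)
    df["status"] = status
    df["icer_vs_previous"] = icers
    return df


def _icer(df: pd.DataFrame, i: int, j: int) -> float | None:
    dq = df.loc[j, "qalys"] - df.loc[i, "qalys"]
    if dq == 0:
        return None
    return (df.loc[j, "cost"] - df.loc[i, "cost"]) / dq


def outcomes_table(outcomes: Mapping[str, EconomicOutcome], comparator: str, wtp: float) -> pd.DataFrame:
    """Base-case results in the layout of a standard CEA summary table:
    component costs, life years and QALYs per strategy, plus increments and
    ICER vs the comparator."""
    rows = []
    comp = outcomes[comparator]
    for name, o in outcomes.items():
        row = {
            "strategy": name,
            "total_cost": o.total_cost,
            "drug_cost": o.drug_cost,
            "monitoring_cost": o.monitoring_cost,
            "ae_cost": o.ae_cost,
            "eol_cost": o.eol_cost,
            "life_years": o.life_years,
            "qalys": o.qalys,
        }
        if name != comparator:
            cmp_res = compare(o, comp, wtp)
            row["incremental_cost"] = cmp_res.incremental_cost
            row["incremental_qalys"] = cmp_res.incremental_qalys
            row["icer_vs_comparator"] = cmp_res.icer if cmp_res.icer is not None else cmp_res.label
        else:
            row["incremental_cost"] = 0.0
            row["incremental_qalys"] = 0.0
            row["icer_vs_comparator"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
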