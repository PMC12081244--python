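"""Deterministic and probabilistic sensitivity analysis, CEAC and EVPI.

One-way DSA reruns the economic evaluation at each parameter's bounds
(defaulting to +/-20% of base when a source range is not given) and ranks
parameters by ICER spread for a tornado display.  PSA draws cost parameters
from gamma and utility/probability parameters from beta distributions whose
moments are matched to the base value and the range (sd = range width /
3.92, a 95%-interval convention), then re-evaluates costs and QALYs per
strategy per draw; survival curves are held at base.  CEAC and EVPI are
computed from net monetary benefit (NMB = WTP x QALYs - cost) over draws.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTrace
from .config import build_settings, build_strategies, build_utilities, set_by_path
from .economics import EconomicOutcome, evaluate_strategy

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "dsa_bounds",
    "build_parameters",
    "moments_to_sampler",
    "evaluate_economics",
    "run_dsa",
    "run_psa",
    "ceac",
    "evpi",
    "ce_plane",
    "default_wtp_grid",
]

_Z95_WIDTH = 2.0 * 1.959963984540054  # 95% normal interval width in sd units


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain scalar: base value, DSA bounds, PSA family."""

    name: str
    path: str  # dotted config path of the base value
    base: float
    low: float
    high: float
    family: str  # "gamma" (costs) | "beta" (utilities / probabilities / rates)

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.family not in ("gamma", "beta"):
            raise ValueError(f"{self.name}: family must be gamma or beta")
        if self.family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta needs values in [0, 1]")
        if self.family == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma needs non-negative values")


@dataclass
class PSAResult:
    """Monte Carlo draws and the (cost, QALY) pairs they produced."""

    draws: pd.DataFrame  # one column per parameter path
    costs: pd.DataFrame  # one column per strategy
    qalys: pd.DataFrame
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.costs)

    @property
    def strategies(self) -> list[str]:
        return list(self.costs.columns)


def dsa_bounds(
    base: float,
    explicit_low: float | None = None,
    explicit_high: float | None = None,
    cap: float | None = None,
) -> tuple[float, float]:
    """Pass explicit bounds through; otherwise +/-20% of base (utilities
    capped at 1 via ``cap``)."""
    low = 0.8 * base if explicit_low is None else explicit_low
    high = 1.2 * base if explicit_high is None else explicit_high
    if cap is not None:
        high = min(high, cap)
    if low > high:
        raise ValueError(f"low {low} > high {high}")
    return low, high


def build_parameters(config: Mapping) -> list[ParameterDistribution]:
    """The DSA/PSA parameter set mirrored from the configuration tables."""
    params: list[ParameterDistribution] = []

    def add(name, path, entry, family):
        params.append(
            ParameterDistribution(
                name=name,
                path=path + ".base",
                base=entry["base"],
                low=min(entry["low"], entry["base"]),
                high=max(entry["high"], entry["base"]),
                family=family,
            )
        )

    add("Utility: PFS", "utilities.pfs", config["utilities"]["pfs"], "beta")
    add("Utility: PD", "utilities.pd", config["utilities"]["pd"], "beta")
    add(
        "Annual discount rate",
        "settings.annual_discount_rate",
        config["settings"]["annual_discount_rate"],
        "beta",
    )
    for drug, entry in config["drug_prices"].items():
        add(f"Drug cost: {drug}", f"drug_prices.{drug}", entry, "gamma")
    for item, entry in config["monitoring"].items():
        add(f"Monitoring cost: {item}", f"monitoring.{item}", entry, "gamma")
    add("End-of-life care cost", "end_of_life", config["end_of_life"], "gamma")
    for ae, entry in config["adverse_events"].items():
        add(f"AE cost: {ae}", f"adverse_events.{ae}.cost", entry["cost"], "gamma")
        add(f"AE disutility: {ae}", f"adverse_events.{ae}.disutility", entry["disutility"], "beta")
    return params


def moments_to_sampler(dist: ParameterDistribution) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Seed-reproducible sampler via method-of-moments from (base, low, high).

    Degenerate ranges (or a zero mean) give a point mass; infeasible beta
    moments fall back to a uniform on the bounds with a warning.
    """
    mean = dist.base
    sd = (dist.high - dist.low) / _Z95_WIDTH
    if sd == 0 or mean == 0 and dist.family == "gamma":
        return lambda rng, size: np.full(size, mean)
    if dist.family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return lambda rng, size: rng.gamma(shape, scale, size)
    # beta
    var = sd**2
    if var >= mean * (1 - mean) or not 0 < mean < 1:
        warnings.warn(
            f"{dist.name}: beta moments infeasible; sampling uniform on bounds", stacklevel=2
        )
        lo, hi = dist.low, dist.high
        return lambda rng, size: rng.uniform(lo, hi, size)
    common = mean * (1 - mean) / var - 1.0
    alpha, beta = mean * common, (1 - mean) * common
    return lambda rng, size: rng.beta(alpha, beta, size)


def evaluate_economics(
    config: Mapping, traces: Mapping[str, CohortTrace]
) -> dict[str, EconomicOutcome]:
    """Economic outcomes per strategy from a config and fixed cohort traces."""
    settings = build_settings(config)
    utilities = build_utilities(config)
    strategies = build_strategies(config)
    return {
        name: evaluate_strategy(traces[name], strat, utilities, settings)
        for name, strat in strategies.items()
    }


def _icer_pair(outcomes: Mapping[str, EconomicOutcome], intervention: str, comparator: str) -> float:
    a, b = outcomes[intervention], outcomes[comparator]
    dq = a.qalys - b.qalys
    return np.nan if dq == 0 else (a.total_cost - b.total_cost) / dq


def run_dsa(
    config: Mapping,
    traces: Mapping[str, CohortTrace],
    intervention: str,
    comparator: str | None = None,
    parameters: Sequence[ParameterDistribution] | None = None,
) -> pd.DataFrame:
    """One-way DSA: rerun the pipeline at each parameter's low and high.

    Returns a tornado table sorted by descending ICER spread, with a flag
    where the base ICER falls outside the two bound ICERs (non-monotone
    response)."""
    comparator = comparator or config["comparator"]
    parameters = parameters if parameters is not None else build_parameters(config)
    base_icer = _icer_pair(evaluate_economics(config, traces), intervention, comparator)
    rows = []
    for p in parameters:
        vals = {}
        for side, v in (("low", p.low), ("high", p.high)):
            cfg = copy.deepcopy(dict(config))
            set_by_path(cfg, p.path, v)
            try:
                with warnings.catch_warnings():
                    warnings.filterwarnings("ignore", message=".*exceeds u_pfs.*")
                    vals[side] = _icer_pair(evaluate_economics(cfg, traces), intervention, comparator)
            except Exception as exc:  # model failure at a bound
                warnings.warn(f"DSA failed for {p.name} at {side}: {exc}", stacklevel=2)
                vals[side] = np.nan
        lo, hi = vals["low"], vals["high"]
        rows.append(
            {
                "parameter": p.name,
                "path": p.path,
                "icer_at_low": lo,
                "icer_at_high": hi,
                "spread": abs(hi - lo),
                "non_monotone": bool(
                    np.isfinite(lo) and np.isfinite(hi) and not (min(lo, hi) <= base_icer <= max(lo, hi))
                ),
            }
        )
    out = pd.DataFrame(rows).sort_values("spread", ascending=False, ignore_index=True)
    out.attrs["base_icer"] = base_icer
    return out


def run_psa(
    config: Mapping,
    traces: Mapping[str, CohortTrace],
    n_iter: int | None = None,
    seed: int = 0,
    parameters: Sequence[ParameterDistribution] | None = None,
) -> PSAResult:
    """Monte Carlo PSA with independent parameter draws (1,000 by default)."""
    n_iter = n_iter if n_iter is not None else config["psa"]["n_iter"]
    parameters = parameters if parameters is not None else build_parameters(config)
    rng = np.random.default_rng(seed)
    draws = pd.DataFrame(
        {p.path: moments_to_sampler(p)(rng, n_iter) for p in parameters}
    )
    strategies = list(config["strategies"])
    costs = np.empty((n_iter, len(strategies)))
    qalys = np.empty((n_iter, len(strategies)))
    base_cfg = copy.deepcopy(dict(config))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*exceeds u_pfs.*")
        for i in range(n_iter):
            cfg = copy.deepcopy(base_cfg)
            for p in parameters:
                set_by_path(cfg, p.path, float(draws.iloc[i][p.path]))
            outcomes = evaluate_economics(cfg, traces)
            for j, s in enumerate(strategies):
                costs[i, j] = outcomes[s].total_cost
                qalys[i, j] = outcomes[s].qalys
    return PSAResult(
        draws=draws,
        costs=pd.DataFrame(costs, columns=strategies),
        qalys=pd.DataFrame(qalys, columns=strategies),
        seed=seed,
    )


def default_wtp_grid(config: Mapping) -> np.ndarray:
    """0 to 3x GDP in the configured number of steps."""
    top = config["wtp"]["thresholds"][-1]
    return np.linspace(0.0, top, config["wtp"]["grid_points"])


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability each strategy maximizes NMB at each WTP.

    NMB ties within a draw are awarded to the cheaper strategy.  The
    probabilities across strategies sum to 1 at every threshold.
    """
    costs = psa.costs.to_numpy()
    qalys = psa.qalys.to_numpy()
    strategies = psa.strategies
    cost_rank = np.argsort(np.argsort(costs, axis=1, kind="stable"), axis=1)
    rows = []
    for w in np.asarray(wtp_grid, dtype=float):
        nmb = w * qalys - costs
        best_nmb = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best_nmb, rtol=0.0, atol=1e-9)
        # among NMB-maximal strategies pick the cheapest
        masked_rank = np.where(is_best, cost_rank, np.iinfo(np.int64).max)
        winner = masked_rank.argmin(axis=1)
        frac = np.bincount(winner, minlength=len(strategies)) / psa.n_iter
        rows.append({"wtp": w, **{s: frac[j] for j, s in enumerate(strategies)}})
    return pd.DataFrame(rows)


def evpi(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Per-patient expected value of perfect information at each WTP:
    E[max_s NMB_s] - max_s E[NMB_s]."""
    costs = psa.costs.to_numpy()
    qalys = psa.qalys.to_numpy()
    rows = []
    for w in np.asarray(wtp_grid, dtype=float):
        nmb = w * qalys - costs
        value = float(nmb.max(axis=1).mean() - nmb.mean(axis=0).max())
        rows.append({"wtp": w, "evpi": max(value, 0.0)})
    return pd.DataFrame(rows)


def ce_plane(psa: PSAResult, intervention: str, comparator: str) -> pd.DataFrame:
    """Per-draw incremental (QALY, cost) scatter of intervention vs comparator."""
    return pd.DataFrame(
        {
            "incremental_qalys": psa.qalys[intervention] - psa.qalys[comparator],
            "incremental_cost": psa.costs[intervention] - psa.costs[comparator],
        }
    )
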