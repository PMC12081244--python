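"""Synthetic two-arm trial data with the structure the downstream model assumes.

Emulates, end to end, the evidence base of a first-line NSCLC trial: patient
level PFS/OS times per arm, their Kaplan-Meier curves, the graph-digitization
step that published analyses apply to figure panels (grid sampling, optional
jitter, monotonization), and numbers-at-risk tables.  Overall survival is
generated as PFS plus a post-progression survival (PPS) increment, which
enforces PFS <= OS patient by patient.

Censoring is administrative at a calendar data cut-off (entry staggered over
an accrual window) plus an optional random-dropout hazard.  Times are months
(1 month = 30.4375 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import distributions as dist

__all__ = [
    "ArmSpec",
    "DigitizedCurve",
    "sample_survival_times",
    "generate_arm_ipd",
    "generate_study_ipd",
    "digitize",
    "at_risk_counts",
    "validate_ipd",
    "write_study",
]

IPD_COLUMNS = ["patient_id", "arm", "endpoint", "time_months", "event"]


@dataclass(frozen=True)
class ArmSpec:
    """Generating description of one trial arm.

    ``pps_family``/``pps_params`` parameterize the post-progression survival
    increment added to PFS to obtain OS.  ``admin_censor_time`` is calendar
    time from study start; per-patient follow-up is that minus the entry time
    drawn uniformly on ``[0, accrual_window]``.  ``dropout_rate`` is a
    per-month hazard of random loss to follow-up (0 disables it).
    """

    name: str
    pfs_family: str
    pfs_params: Mapping[str, float]
    pps_family: str = "exponential"
    pps_params: Mapping[str, float] = field(default_factory=lambda: {"shape": 1.0, "scale": 24.0})
    n_patients: int = 429
    accrual_window: float = 0.0
    admin_censor_time: float = 42.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.accrual_window < 0 or self.dropout_rate < 0:
            raise ValueError("accrual_window and dropout_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0 (use np.inf for none)")
        for fam, par in ((self.pfs_family, self.pfs_params), (self.pps_family, self.pps_params)):
            dist.validate_params(fam, par.get("shape", 1.0), par["scale"])


@dataclass
class DigitizedCurve:
    """Grid-sampled coordinates of a survival curve, as read off a figure."""

    endpoint: str
    arm: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: pd.DataFrame | None = None  # columns time_months, n_at_risk

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.size == 0:
            raise ValueError("digitized curve has no points")
        if self.times[0] != 0.0 or abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("digitized curve must start at (0, 1)")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("digitized survival must be non-increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


def sample_survival_times(
    family: str, params: Mapping[str, float], n: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from one family; ``params`` holds ``shape``/``scale``."""
    rng = _as_rng(rng_seed)
    return dist.rvs(family, params.get("shape", 1.0), params["scale"], n, rng)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_arm_ipd(spec: ArmSpec, rng_seed: int | np.random.Generator) -> pd.DataFrame:
    """Individual patient data (long format, one row per patient x endpoint)."""
    rng = _as_rng(rng_seed)
    n = spec.n_patients
    pfs = dist.rvs(spec.pfs_family, spec.pfs_params.get("shape", 1.0), spec.pfs_params["scale"], n, rng)
    pps = dist.rvs(spec.pps_family, spec.pps_params.get("shape", 1.0), spec.pps_params["scale"], n, rng)
    os_time = pfs + pps

    entry = rng.uniform(0.0, spec.accrual_window, n) if spec.accrual_window > 0 else np.zeros(n)
    followup = np.maximum(spec.admin_censor_time - entry, 1e-6)
    if spec.dropout_rate > 0:
        dropout = rng.exponential(1.0 / spec.dropout_rate, n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(followup, dropout)

    frames = []
    for endpoint, times in (("PFS", pfs), ("OS", os_time)):
        obs = np.minimum(times, censor)
        event = (times <= censor).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(n),
                    "arm": spec.name,
                    "endpoint": endpoint,
                    "time_months": obs,
                    "event": event,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_study_ipd(
    arm_specs: Mapping[str, ArmSpec], rng_seed: int
) -> pd.DataFrame:
    """All arms, with one spawned random stream per arm (order-stable)."""
    seq = np.random.SeedSequence(rng_seed)
    children = seq.spawn(len(arm_specs))
    frames = []
    for child, (name, spec) in zip(children, sorted(arm_specs.items())):
        df = generate_arm_ipd(spec, np.random.default_rng(child))
        df["patient_id"] = name + "-" + df["patient_id"].astype(str)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def validate_ipd(ipd: pd.DataFrame) -> None:
    """Check the IPD contract: finite positive times, 0/1 events, PFS <= OS."""
    missing = set(IPD_COLUMNS) - set(ipd.columns)
    if missing:
        raise ValueError(f"IPD missing columns: {sorted(missing)}")
    t = ipd["time_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("IPD times must be finite and > 0")
    if not set(np.unique(ipd["event"])) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    wide = ipd.pivot_table(index=["patient_id", "arm"], columns="endpoint", values="time_months")
    if {"PFS", "OS"} <= set(wide.columns):
        both = wide.dropna(subset=["PFS", "OS"])
        if np.any(both["PFS"].to_numpy() > both["OS"].to_numpy() + 1e-9):
            raise ValueError("found a patient with PFS time > OS time")


def digitize(
    km_curve,
    grid_spacing: float,
    jitter_sd: float = 0.0,
    rng_seed: int | np.random.Generator | None = None,
    endpoint: str = "",
    arm: str = "",
) -> DigitizedCurve:
    """Simulate reading a KM curve off a published figure.

    Evaluates the step function on a regular time grid, optionally perturbs
    the survival ordinates with Gaussian jitter (digitization error), clips to
    [0, 1], monotonizes by a running minimum, and pins the first point to
    (0, 1).  ``km_curve`` is any object with ``evaluate(times)`` and
    ``max_time`` (see :class:`survecon.fitting.KMCurve`).
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    tmax = float(km_curve.max_time)
    if not np.isfinite(tmax) or tmax <= 0:
        raise ValueError("empty or degenerate step function")
    n_steps = int(np.floor(tmax / grid_spacing + 1e-9))
    grid = grid_spacing * np.arange(n_steps + 1)
    if grid[-1] < tmax - 1e-9:
        grid = np.append(grid, tmax)
    vals = np.asarray(km_curve.evaluate(grid), dtype=float)
    if jitter_sd > 0:
        rng = _as_rng(rng_seed if rng_seed is not None else 0)
        vals = vals + rng.normal(0.0, jitter_sd, size=vals.shape)
    vals = np.clip(vals, 0.0, 1.0)
    vals = np.minimum.accumulate(vals)
    vals[0] = 1.0
    return DigitizedCurve(endpoint=endpoint, arm=arm, times=grid, survival=vals)


def at_risk_counts(ipd: pd.DataFrame, report_times: Sequence[float]) -> pd.DataFrame:
    """Numbers still under observation (time >= t) at each report time."""
    report_times = np.asarray(report_times, dtype=float)
    if np.any(np.diff(report_times) < 0):
        raise ValueError("report_times must be ascending")
    t = np.sort(ipd["time_months"].to_numpy(dtype=float))
    counts = t.size - np.searchsorted(t, report_times, side="left")
    return pd.DataFrame({"time_months": report_times, "n_at_risk": counts.astype(int)})


def write_study(
    arm_specs: Mapping[str, ArmSpec],
    rng_seed: int,
    outdir: str | Path,
    grid_spacing: float = 1.0,
    jitter_sd: float = 0.0,
    at_risk_spacing: float = 3.0,
) -> dict[str, Path]:
    """Emit a complete synthetic study directory (IPD, digitized curves, at-risk).

    Returns a mapping of logical names to written CSV paths.
    """
    from .fitting import km_estimate  # deferred: fitting imports lifelines

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ipd = generate_study_ipd(arm_specs, rng_seed)
    paths: dict[str, Path] = {}
    ipd_path = outdir / "ipd.csv"
    ipd.to_csv(ipd_path, index=False)
    paths["ipd"] = ipd_path

    jit_rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0]) if jitter_sd > 0 else None
    for (arm, endpoint), sub in ipd.groupby(["arm", "endpoint"], sort=True):
        km = km_estimate(sub)
        curve = digitize(km, grid_spacing, jitter_sd, jit_rng, endpoint=endpoint, arm=arm)
        stem = f"{arm}_{endpoint.lower()}"
        curve_path = outdir / f"curve_{stem}.csv"
        curve.to_frame().to_csv(curve_path, index=False)
        paths[f"curve_{stem}"] = curve_path
        grid = np.arange(0.0, km.max_time + at_risk_spacing, at_risk_spacing)
        risk = at_risk_counts(sub, grid)
        risk_path = outdir / f"at_risk_{stem}.csv"
        risk.to_csv(risk_path, index=False)
        paths[f"at_risk_{stem}"] = risk_path
    return paths
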