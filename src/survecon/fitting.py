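"""Survival estimation: KM curves, pseudo-IPD reconstruction, parametric MLE.

The pipeline mirrors how published cost-utility analyses treat trial figures:
a Kaplan-Meier product-limit estimate (via lifelines), an interval-wise
reconstruction of approximate patient-level data from digitized curve
coordinates and numbers-at-risk (the standard Guyot-style allocation of
events and censorings), censored maximum-likelihood fits of six parametric
families, and AIC/BIC model selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.optimize import minimize

from . import distributions as dist
from .distributions import FAMILIES, ParameterError, n_params

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "ParametricSurvivalModel",
    "FitReport",
    "km_estimate",
    "reconstruct_pseudo_ipd",
    "fit_family",
    "fit_all",
    "select_model",
    "survival_at",
    "median_survival",
    "cox_hazard_ratio",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate as a right-continuous step function."""

    times: np.ndarray  # includes 0
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    @property
    def max_time(self) -> float:
        return float(self.times[-1])

    def evaluate(self, t) -> np.ndarray:
        """Step-function value S(t) (previous-point interpolation)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.survival[idx]

    @property
    def median(self) -> float:
        below = self.survival <= 0.5 + 1e-12
        return float(self.times[below][0]) if below.any() else float("inf")


def km_estimate(ipd: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate of a single-endpoint IPD table.

    ``ipd`` needs columns ``time_months`` and ``event``.  All-censored input
    yields a flat curve; empty input is an error.
    """
    if len(ipd) == 0:
        raise ValueError("cannot estimate a survival curve from empty data")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"], ipd["event"])
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    if times[0] != 0.0:  # lifelines normally inserts t=0 itself
        times = np.insert(times, 0, 0.0)
        table = pd.concat([pd.DataFrame({"at_risk": [len(ipd)], "observed": [0]}, index=[0.0]), table])
    surv = kmf.predict(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        n_at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
    )


def cox_hazard_ratio(
    ipd: pd.DataFrame, endpoint: str = "PFS", reference_arm: str | None = None
) -> float:
    """Proportional-hazards HR of the non-reference arm vs the reference.

    Expects a two-arm IPD table; the reference defaults to the
    lexicographically later arm name so that, with the packaged arms
    (combination, osimertinib), the HR reported is combination vs
    osimertinib.
    """
    sub = ipd[ipd["endpoint"] == endpoint] if "endpoint" in ipd.columns else ipd
    arms = sorted(sub["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"expected exactly two arms, got {arms}")
    if reference_arm is None:
        reference_arm = arms[-1]
    df = pd.DataFrame(
        {
            "time": sub["time_months"].to_numpy(dtype=float),
            "event": sub["event"].to_numpy(dtype=int),
            "treat": (sub["arm"] != reference_arm).astype(int).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["treat"]))


# ---------------------------------------------------------------------------
# Pseudo-IPD reconstruction (interval-wise event/censor allocation)
# ---------------------------------------------------------------------------


def reconstruct_pseudo_ipd(
    curve,
    at_risk: pd.DataFrame | None = None,
    total_events: int | None = None,
    n_start: int | None = None,
) -> pd.DataFrame:
    """Recover approximate patient-level data from digitized KM coordinates.

    Within each interval between consecutive numbers-at-risk reports, events
    are allocated at the digitized time points by inverting the product-limit
    recursion, and censorings are spread uniformly over the interval; the
    censoring count is iterated until the implied risk set at the start of
    the next interval matches the published number.  Subjects still at risk
    after the last coordinate are censored there.

    Without an at-risk table the reconstruction falls back to an event-only
    scheme (no interior censoring) starting from ``n_start`` (or
    ``total_events``) subjects, with a logged warning.
    """
    t = np.asarray(curve.times, dtype=float)
    S = np.asarray(curve.survival, dtype=float)
    order = np.argsort(t, kind="stable")
    t, S = t[order], S[order]
    keep = np.concatenate(([True], np.diff(t) > 1e-12))
    t, S = t[keep], S[keep]
    S = np.clip(S, 0.0, 1.0)
    rises = np.diff(S)
    if np.any(rises > 0.01):
        raise ValueError("digitized curve is non-monotone beyond cleaning tolerance")
    S = np.minimum.accumulate(S)
    if t[0] > 0:
        t = np.insert(t, 0, 0.0)
        S = np.insert(S, 0, 1.0)
    S[0] = 1.0
    N = len(t)

    if at_risk is None and getattr(curve, "at_risk", None) is not None:
        at_risk = curve.at_risk
    if at_risk is None:
        logger.warning("no at-risk table: falling back to event-only reconstruction")
        n0 = n_start or total_events or 100
        risk_t = np.array([0.0])
        risk_n = np.array([n0])
    else:
        risk_t = np.asarray(at_risk["time_months"], dtype=float)
        risk_n = np.asarray(at_risk["n_at_risk"], dtype=int)
        if len(risk_t) < 2:
            raise ValueError("at-risk table needs counts at >= 2 times")
        if np.any(np.diff(risk_n) > 0):
            raise ValueError("at-risk counts must be non-increasing")
        if risk_t[0] > 0:
            risk_t = np.insert(risk_t, 0, 0.0)
            risk_n = np.insert(risk_n, 0, risk_n[0])
        # drop trailing reports beyond the digitized range
        keep_r = risk_t <= t[-1] + 1e-9
        risk_t, risk_n = risk_t[keep_r], risk_n[keep_r]

    M = len(risk_t)
    lower = np.searchsorted(t, risk_t, side="left")
    lower[0] = 0

    event_counts = np.zeros(N, dtype=int)
    censor_times: list[float] = []
    km_prev = 1.0
    n_curr = int(risk_n[0])

    for i in range(M):
        lo = int(lower[i])
        hi = int(lower[i + 1]) - 1 if i < M - 1 else N - 1
        if hi < lo:
            continue
        t_end = risk_t[i + 1] if i < M - 1 else t[-1] + 1e-9
        target = int(risk_n[i + 1]) if i < M - 1 else None

        c = 0
        best = None
        for _ in range(60):
            res = _allocate_interval(t, S, lo, hi, n_curr, km_prev, c, risk_t[i], t_end)
            n_end = res[0]
            if target is None:
                best = res
                break
            gap = n_end - target
            if best is None or abs(gap) < abs(best[0] - target):
                best = res
            if gap == 0:
                break
            c = max(c + gap, 0)
            if c > n_curr:
                c = n_curr
        n_end, d_int, ctimes, km_end = best
        event_counts[lo : hi + 1] += d_int
        censor_times.extend(ctimes)
        km_prev = km_end
        n_curr = n_end
        if target is not None:
            n_curr = target if abs(n_curr - target) <= 1 else n_curr

    records = []
    for k in range(N):
        for _ in range(event_counts[k]):
            records.append((t[k], 1))
    for ct in censor_times:
        records.append((ct, 0))
    for _ in range(max(n_curr, 0)):
        records.append((t[-1], 0))

    out = pd.DataFrame(records, columns=["time_months", "event"]).sort_values(
        ["time_months", "event"], ignore_index=True
    )
    out["time_months"] = out["time_months"].clip(lower=1e-6)
    out.insert(0, "patient_id", np.arange(len(out)))
    for col, val in (("arm", getattr(curve, "arm", "")), ("endpoint", getattr(curve, "endpoint", ""))):
        if val:
            out[col] = val
    return out


def _allocate_interval(t, S, lo, hi, n_start, km_prev, n_cens, t0, t1):
    """Walk the digitized clicks of one interval, allocating events/censors."""
    ctimes = t0 + np.arange(1, n_cens + 1) * (t1 - t0) / (n_cens + 1) if n_cens > 0 else np.empty(0)
    n = n_start
    km = km_prev
    d_out = np.zeros(hi - lo + 1, dtype=int)
    used_c: list[float] = []
    for k in range(lo, hi + 1):
        if n > 0 and km > 0:
            d = int(round(n * (1.0 - S[k] / km)))
            d = min(max(d, 0), n)
        else:
            d = 0
        if d > 0:
            km *= 1.0 - d / n
            n -= d
        d_out[k - lo] = d
        nxt = t[k + 1] if k < hi else t1
        in_gap = ctimes[(ctimes >= t[k] - 1e-12) & (ctimes < nxt - 1e-12)]
        take = min(len(in_gap), n)
        used_c.extend(in_gap[:take].tolist())
        n -= take
    return n, d_out, used_c, km


# ---------------------------------------------------------------------------
# Parametric maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class ParametricSurvivalModel:
    """A fitted family with its censored log-likelihood and AIC/BIC."""

    family: str
    shape: float
    scale: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool = True

    def survival_at(self, t):
        return dist.sf(self.family, self.shape, self.scale, t)

    def median(self) -> float:
        return dist.median(self.family, self.shape, self.scale)


def survival_at(model: ParametricSurvivalModel, t):
    """S(t) for a fitted model (module-level convenience)."""
    return model.survival_at(t)


def median_survival(model: ParametricSurvivalModel) -> float:
    return model.median()


@dataclass
class FitReport:
    """Per-family fits plus the criterion-minimizing selection."""

    models: dict[str, ParametricSurvivalModel]
    selected_family: str
    selection_criterion: str = "aic"

    @property
    def selected(self) -> ParametricSurvivalModel:
        return self.models[self.selected_family]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": m.family,
                "shape": m.shape,
                "scale": m.scale,
                "loglik": m.loglik,
                "aic": m.aic,
                "bic": m.bic,
                "converged": m.converged,
                "selected": m.family == self.selected_family,
            }
            for m in self.models.values()
        ]
        return pd.DataFrame(rows)


def _negloglik(family, theta, times, events):
    shape, scale = _unpack(family, theta)
    try:
        dist.validate_params(family, shape, scale)
    except ParameterError:
        return np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        ll_e = dist.logpdf(family, shape, scale, times[events == 1]) if np.any(events == 1) else 0.0
        ll_c = dist.logsf(family, shape, scale, times[events == 0]) if np.any(events == 0) else 0.0
    total = np.sum(ll_e) + np.sum(ll_c)
    return np.inf if not np.isfinite(total) else -float(total)


def _unpack(family, theta):
    if family == "exponential":
        return 1.0, float(np.exp(theta[0]))
    if family == "gompertz":
        return float(theta[0]), float(np.exp(theta[1]))
    return float(np.exp(theta[0])), float(np.exp(theta[1]))


def _starts(family, times, events):
    """Three moment-flavoured starting points per family (log-scale packed)."""
    ev_times = times[events == 1]
    anchor = float(np.median(ev_times)) if ev_times.size else float(np.median(times))
    anchor = max(anchor, 1e-3)
    total, n_ev = float(times.sum()), max(int(events.sum()), 1)
    exp_scale = max(total / n_ev, 1e-3)
    if family == "exponential":
        return [np.array([np.log(s)]) for s in (exp_scale, anchor / np.log(2), 2 * exp_scale)]
    if family == "gompertz":
        return [np.array([s, np.log(exp_scale)]) for s in (-0.02, 1e-3, 0.05)]
    if family == "lognormal":
        logs = np.log(np.maximum(ev_times if ev_times.size else times, 1e-6))
        mu, sigma = float(np.mean(logs)), max(float(np.std(logs)), 0.1)
        return [
            np.array([np.log(sigma), mu]),
            np.array([np.log(1.0), np.log(anchor)]),
            np.array([np.log(0.5), mu]),
        ]
    return [np.array([np.log(sh), np.log(anchor / np.log(2) if family == "weibull" else anchor)]) for sh in (0.8, 1.0, 1.5)]


def fit_family(ipd: pd.DataFrame, family: str) -> ParametricSurvivalModel:
    """Censored MLE of one family on single-endpoint IPD.

    Optimizes over log-scale parameters (raw shape for Gompertz) with three
    starts; non-convergence across all starts is flagged rather than raised.
    """
    times = ipd["time_months"].to_numpy(dtype=float)
    events = ipd["event"].to_numpy(dtype=int)
    k = n_params(family)
    n_ev = int(events.sum())
    if n_ev < (1 if family == "exponential" else 2):
        raise ValueError(f"{family}: needs >= {1 if k == 1 else 2} events, got {n_ev}")
    if np.ptp(times) < 1e-12:
        raise ValueError("degenerate data: all observation times equal")

    best = None
    for x0 in _starts(family, times, events):
        res = minimize(
            lambda th: _negloglik(family, th, times, events),
            x0,
            method="Nelder-Mead",
            options={"fatol": 1e-10, "xatol": 1e-9, "maxiter": 4000, "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success and np.isfinite(best.fun))
    shape, scale = _unpack(family, best.x)
    ll = -float(best.fun)
    n = len(times)
    return ParametricSurvivalModel(
        family=family,
        shape=shape,
        scale=scale,
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        n_obs=n,
        converged=converged,
    )


def fit_all(ipd: pd.DataFrame, families=FAMILIES, criterion: str = "aic") -> FitReport:
    """Fit every family and select by the criterion (AIC default, BIC reported)."""
    models: dict[str, ParametricSurvivalModel] = {}
    for fam in families:
        try:
            models[fam] = fit_family(ipd, fam)
        except ValueError as exc:
            warnings.warn(f"{fam} fit skipped: {exc}", stacklevel=2)
    selected = select_model(models, criterion)
    return FitReport(models=models, selected_family=selected, selection_criterion=criterion)


def select_model(models: dict[str, ParametricSurvivalModel], criterion: str = "aic") -> str:
    """Argmin of AIC or BIC over converged fits; ties go to the earlier family
    in the fixed order (exponential first: fewest parameters)."""
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    best_fam, best_val = None, np.inf
    for fam in FAMILIES:
        m = models.get(fam)
        if m is None or not m.converged:
            continue
        val = getattr(m, criterion)
        if val < best_val:  # strict: earlier family keeps ties
            best_fam, best_val = fam, val
    if best_fam is None:
        raise ValueError("no converged fit to select from")
    return best_fam
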