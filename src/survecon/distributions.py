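"""Parametric survival families used for extrapolating trial endpoints.

Six right-skewed families share a common ``(shape, scale)`` axis, written
``lam`` (shape, dimensionless except Gompertz where it is per month) and
``gamma`` (scale, months).  The survival functions are fixed as:

============  =======================================================
exponential   ``S(t) = exp(-t / gamma)``                     (1 param)
weibull       ``S(t) = exp(-(t / gamma)**lam)``
gompertz      ``S(t) = exp(-(exp(lam*t) - 1) / (lam*gamma))``
loglogistic   ``S(t) = 1 / (1 + (t / gamma)**lam)``
lognormal     ``S(t) = 1 - Phi(log(t / gamma) / lam)``
gamma         ``S(t) = Q(lam, t / gamma)``  (upper regularized)
============  =======================================================

With these conventions ``gamma`` is the median for the log-logistic and
log-normal families, Weibull with ``lam = 1`` collapses to the exponential,
and Gompertz tends to the exponential as ``lam -> 0``.  Gompertz shape may
be any real number (negative shape gives a decelerating hazard with a
survival plateau ``exp(1/(lam*gamma))``); all other shapes and every scale
must be strictly positive.

Sampling is by inverse transform of the survival function, so draws are
reproducible given a seeded generator and are monotone in the underlying
uniforms.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

FAMILIES: tuple[str, ...] = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gamma",
)

#: shape values |lam| below this are treated as the exponential limit of Gompertz
_GOMPERTZ_EPS = 1e-10


class ParameterError(ValueError):
    """Invalid family identifier or parameter values."""


def n_params(family: str) -> int:
    """Number of free parameters (1 for exponential, 2 otherwise)."""
    _check_family(family)
    return 1 if family == "exponential" else 2


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}; expected one of {FAMILIES}")


def validate_params(family: str, shape: float, scale: float) -> None:
    _check_family(family)
    if not np.isfinite(scale) or scale <= 0:
        raise ParameterError(f"{family}: scale must be finite and > 0, got {scale!r}")
    if not np.isfinite(shape):
        raise ParameterError(f"{family}: shape must be finite, got {shape!r}")
    if family not in ("exponential", "gompertz") and shape <= 0:
        raise ParameterError(f"{family}: shape must be > 0, got {shape!r}")


def sf(family: str, shape: float, scale: float, t) -> np.ndarray | float:
    """Survival function S(t); ``t`` in months, ``t >= 0``."""
    validate_params(family, shape, scale)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival requested at negative time")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.exp(_logsf_arr(family, shape, scale, t))
    return float(out[0]) if scalar else out


def logsf(family: str, shape: float, scale: float, t) -> np.ndarray | float:
    validate_params(family, shape, scale)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = _logsf_arr(family, shape, scale, np.atleast_1d(t))
    return float(out[0]) if scalar else out


def _logsf_arr(family, shape, scale, t):
    if family == "exponential":
        return -t / scale
    if family == "weibull":
        return -np.power(t / scale, shape)
    if family == "gompertz":
        if abs(shape) < _GOMPERTZ_EPS:
            return -t / scale
        return -np.expm1(shape * t) / (shape * scale)
    if family == "loglogistic":
        return stats.fisk.logsf(t, shape, scale=scale)
    if family == "lognormal":
        with np.errstate(divide="ignore"):
            return stats.lognorm.logsf(t, shape, scale=scale)
    # gamma
    with np.errstate(divide="ignore"):
        return np.log(special.gammaincc(shape, t / scale))


def logpdf(family: str, shape: float, scale: float, t) -> np.ndarray | float:
    """Log density; ``t > 0``."""
    validate_params(family, shape, scale)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if family == "exponential":
        out = -np.log(scale) - t / scale
    elif family == "weibull":
        out = stats.weibull_min.logpdf(t, shape, scale=scale)
    elif family == "gompertz":
        if abs(shape) < _GOMPERTZ_EPS:
            out = -np.log(scale) - t / scale
        else:
            # hazard h(t) = exp(shape*t)/scale
            out = shape * t - np.log(scale) - np.expm1(shape * t) / (shape * scale)
    elif family == "loglogistic":
        out = stats.fisk.logpdf(t, shape, scale=scale)
    elif family == "lognormal":
        out = stats.lognorm.logpdf(t, shape, scale=scale)
    else:
        out = stats.gamma.logpdf(t, shape, scale=scale)
    return float(out[0]) if scalar else out


def isf(family: str, shape: float, scale: float, u) -> np.ndarray | float:
    """Inverse survival: the time ``t`` with ``S(t) = u``, ``u`` in (0, 1]."""
    validate_params(family, shape, scale)
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    if np.any((u <= 0) | (u > 1)):
        raise ValueError("inverse survival needs u in (0, 1]")
    if family == "exponential":
        out = -scale * np.log(u)
    elif family == "weibull":
        out = scale * np.power(-np.log(u), 1.0 / shape)
    elif family == "gompertz":
        if abs(shape) < _GOMPERTZ_EPS:
            out = -scale * np.log(u)
        else:
            arg = 1.0 - shape * scale * np.log(u)
            out = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / shape, np.inf)
    elif family == "loglogistic":
        out = scale * np.power((1.0 - u) / u, 1.0 / shape)
    elif family == "lognormal":
        out = scale * np.exp(shape * stats.norm.isf(u))
    else:
        out = scale * special.gammainccinv(shape, u)
    return float(out[0]) if scalar else out


def median(family: str, shape: float, scale: float) -> float:
    """Median survival in months (``inf`` for a Gompertz plateau above 0.5)."""
    return float(isf(family, shape, scale, 0.5))


def rvs(family: str, shape: float, scale: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` inverse-transform draws using uniforms from ``rng``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random(n)
    # u plays the role of S(t); guard the measure-zero endpoints
    u = np.clip(u, 1e-15, 1.0)
    return np.asarray(isf(family, shape, scale, u), dtype=float)
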