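"""Default model configuration and config-dict plumbing.

The configuration is a plain nested dict (YAML-serializable) mirroring the
published parameter table field for field: per-cycle drug acquisition costs,
monitoring items with billing frequencies, end-of-life care, adverse-event
management costs and disutilities, health-state utilities, discounting, and
willingness-to-pay thresholds, all in 2023 USD (converted at 1 USD =
7.08 CNY upstream of this package; the conversion is a constant here, not a
computation).

The synthetic-arm section is calibrated so that the generating curves carry
the trial's headline efficacy: a proportional-hazards Weibull pair sharing
shape ``ln(1/0.70) / ln(23.7/16.6)``, which reproduces median PFS of 23.7
months (combination) and 16.6 months (osimertinib) and a hazard ratio of
exactly 0.70.  The lazertinib strategy reuses the osimertinib arm's curves
as a proxy.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from typing import Any, Mapping

from .cohort import ModelSettings
from .economics import AdverseEvent, StrategySpec, UtilitySet
from .simulate import ArmSpec

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "get_by_path",
    "set_by_path",
    "list_paths",
    "config_hash",
    "build_settings",
    "build_utilities",
    "build_strategies",
    "build_arm_specs",
    "WTP_THRESHOLDS",
    "WTP_THRESHOLDS_ALTERNATE",
]

#: 1x and 3x China 2023 per-capita GDP (USD/QALY), abstract values (default)
WTP_THRESHOLDS = (12_295.7, 36_887.0)
#: the alternative printed pair, shipped for completeness
WTP_THRESHOLDS_ALTERNATE = (12_621.19, 37_863.51)

# Proportional-hazards Weibull calibration: shared shape, HR 0.70,
# medians 23.7 / 16.6 months.
_PH_SHAPE = math.log(1 / 0.70) / math.log(23.7 / 16.6)
_SCALE_COMBINATION = 23.7 / math.log(2.0) ** (1.0 / _PH_SHAPE)
_SCALE_OSIMERTINIB = 16.6 / math.log(2.0) ** (1.0 / _PH_SHAPE)


def _p(base: float, low: float, high: float) -> dict[str, float]:
    return {"base": base, "low": low, "high": high}


_DEFAULT: dict[str, Any] = {
    "settings": {
        "cycle_length_days": 21.0,
        "horizon_years": 5.0,
        "annual_discount_rate": _p(0.03, 0.0, 0.05),
        "half_cycle_correction": False,
    },
    "wtp": {
        "thresholds": list(WTP_THRESHOLDS),
        "alternate_thresholds": list(WTP_THRESHOLDS_ALTERNATE),
        "evpi_max": 300_000.0,
        "grid_points": 100,
    },
    "utilities": {
        "pfs": _p(0.71, 0.57, 0.85),
        "pd": _p(0.67, 0.47, 0.71),
    },
    "drug_prices": {  # USD per 21-day cycle
        "amivantamab": _p(17_418.13, 13_982.50, 20_973.75),
        "lazertinib": _p(13_420.47, 10_736.38, 16_104.56),
        "osimertinib": _p(12_623.80, 10_099.04, 15_148.56),
    },
    "monitoring": {  # unit cost billed every n cycles, in the given state
        "outpatient": {**_p(104.41, 83.53, 125.30), "every_n_cycles": 1, "state": "pfs"},
        "follow_up": {**_p(542.62, 406.99, 678.31), "every_n_cycles": 1, "state": "pfs"},
        "laboratory": {**_p(340.20, 272.16, 408.24), "every_n_cycles": 2, "state": "pfs"},
        "mri": {**_p(95.27, 48.9, 190.5), "every_n_cycles": 4, "state": "pfs"},
        "best_supportive_care": {**_p(3_006.28, 2_254.71, 3_757.85), "every_n_cycles": 1, "state": "pd"},
    },
    "end_of_life": _p(40_708.33, 30_531.25, 50_885.41),
    "adverse_events": {
        "paronychia": {"cost": _p(9_396.0, 7_516.8, 11_275.2), "disutility": _p(0.040, 0.032, 0.048)},
        "rash": {"cost": _p(400.0, 320.0, 480.0), "disutility": _p(0.03, 0.02, 0.04)},
        "hypoalbuminemia": {"cost": _p(3_000.0, 2_400.0, 3_600.0), "disutility": _p(0.03, 0.02, 0.04)},
        "alt_ast_increase": {"cost": _p(0.0, 0.0, 0.0), "disutility": _p(0.0, 0.0, 0.0)},
        "dermatitis_acneiform": {"cost": _p(6.9, 5.2, 8.7), "disutility": _p(0.1, 0.08, 0.12)},
        "pulmonary_embolism": {"cost": _p(7_055.0, 5_644.0, 8_466.0), "disutility": _p(0.2, 0.16, 0.24)},
    },
    # grade >=3 incidence proportions per strategy (not varied in DSA/PSA)
    "ae_incidence": {
        "amivantamab_lazertinib": {
            "paronychia": 0.11,
            "rash": 0.08,
            "hypoalbuminemia": 0.05,
            "alt_ast_increase": 0.05,
            "dermatitis_acneiform": 0.08,
            "pulmonary_embolism": 0.09,
        },
        "lazertinib": {
            "paronychia": 0.04,
            "rash": 0.03,
            "hypoalbuminemia": 0.02,
            "alt_ast_increase": 0.03,
            "dermatitis_acneiform": 0.02,
            "pulmonary_embolism": 0.02,
        },
        "osimertinib": {
            "paronychia": 0.005,
            "rash": 0.01,
            "hypoalbuminemia": 0.01,
            "alt_ast_increase": 0.02,
            "dermatitis_acneiform": 0.01,
            "pulmonary_embolism": 0.02,
        },
    },
    "strategies": {
        "amivantamab_lazertinib": {"drugs": ["amivantamab", "lazertinib"], "arm": "combination"},
        "lazertinib": {"drugs": ["lazertinib"], "arm": "osimertinib"},
        "osimertinib": {"drugs": ["osimertinib"], "arm": "osimertinib"},
    },
    "comparator": "osimertinib",
    "synthetic": {
        "arms": {
            "combination": {
                "pfs_family": "weibull",
                "pfs_params": {"shape": _PH_SHAPE, "scale": _SCALE_COMBINATION},
                "pps_family": "exponential",
                "pps_params": {"shape": 1.0, "scale": 36.0},
                "n_patients": 429,
                "accrual_window": 0.0,
                "admin_censor_time": 42.0,
                "dropout_rate": 0.0,
            },
            "osimertinib": {
                "pfs_family": "weibull",
                "pfs_params": {"shape": _PH_SHAPE, "scale": _SCALE_OSIMERTINIB},
                "pps_family": "exponential",
                "pps_params": {"shape": 1.0, "scale": 24.0},
                "n_patients": 429,
                "accrual_window": 0.0,
                "admin_censor_time": 42.0,
                "dropout_rate": 0.0,
            },
        },
        "digitize": {"grid_spacing": 1.0, "jitter_sd": 0.0, "at_risk_spacing": 3.0},
    },
    "fitting": {"criterion": "aic"},
    "psa": {"n_iter": 1000},
}


def default_config() -> dict[str, Any]:
    """A fresh copy of the packaged base-case configuration."""
    return copy.deepcopy(_DEFAULT)


def load_config(path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: Mapping[str, Any], path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dotted-path access
# ---------------------------------------------------------------------------


def get_by_path(config: Mapping[str, Any], path: str):
    node = config
    for part in path.split("."):
        if not isinstance(node, Mapping) or part not in node:
            raise KeyError(f"no such config path: {path!r}")
        node = node[part]
    return node


def set_by_path(config: dict, path: str, value) -> None:
    parts = path.split(".")
    node = config
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise KeyError(f"no such config path: {path!r}")
        node = node[part]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise KeyError(f"no such config path: {path!r}")
    node[parts[-1]] = value


def list_paths(config: Mapping[str, Any], prefix: str = "") -> list[str]:
    out = []
    for key, val in config.items():
        path = f"{prefix}.{key}" if prefix else str(key)
        if isinstance(val, Mapping):
            out.extend(list_paths(val, path))
        else:
            out.append(path)
    return out


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# builders: config dict -> domain objects
# ---------------------------------------------------------------------------


def build_settings(config: Mapping[str, Any]) -> ModelSettings:
    s = config["settings"]
    return ModelSettings(
        cycle_length_days=s["cycle_length_days"],
        horizon_years=s["horizon_years"],
        annual_discount_rate=s["annual_discount_rate"]["base"],
        half_cycle_correction=s["half_cycle_correction"],
    )


def build_utilities(config: Mapping[str, Any]) -> UtilitySet:
    u = config["utilities"]
    return UtilitySet(pfs=u["pfs"]["base"], pd=u["pd"]["base"])


def build_strategies(config: Mapping[str, Any]) -> dict[str, StrategySpec]:
    monitoring = config["monitoring"]
    pfs_items = {
        name: item["base"] / item["every_n_cycles"]
        for name, item in monitoring.items()
        if item["state"] == "pfs"
    }
    pd_items = {
        name: item["base"] / item["every_n_cycles"]
        for name, item in monitoring.items()
        if item["state"] == "pd"
    }
    eol = config["end_of_life"]["base"]
    strategies: dict[str, StrategySpec] = {}
    for name, spec in config["strategies"].items():
        drug_cost = sum(config["drug_prices"][d]["base"] for d in spec["drugs"])
        incid = config["ae_incidence"].get(name, {})
        ae_profile = tuple(
            AdverseEvent(
                name=ae,
                incidence=p,
                cost=config["adverse_events"][ae]["cost"]["base"],
                disutility=config["adverse_events"][ae]["disutility"]["base"],
            )
            for ae, p in incid.items()
        )
        strategies[name] = StrategySpec(
            name=name,
            drug_cost_per_cycle=drug_cost,
            pfs_cycle_cost_items=pfs_items,
            pd_cycle_cost_items=pd_items,
            end_of_life_cost=eol,
            ae_profile=ae_profile,
        )
    return strategies


def build_arm_specs(config: Mapping[str, Any]) -> dict[str, ArmSpec]:
    arms = {}
    for name, raw in config["synthetic"]["arms"].items():
        arms[name] = ArmSpec(name=name, **raw)
    return arms
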