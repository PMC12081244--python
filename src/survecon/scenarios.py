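"""Scenario analysis, config validation, and end-to-end orchestration.

A scenario is a named set of dotted-path overrides applied to a deep copy of
the base configuration.  Three scenarios are packaged: (1) osimertinib
repriced at its Chinese medical-insurance unit cost, (2) lazertinib priced
up by 50%, and (3) alternative health-state utilities; each override also
refreshes the parameter's +/-20% sensitivity bounds.

``run_full_analysis`` drives the whole pipeline from a config and a seed:
synthetic trial generation -> digitization -> pseudo-IPD reconstruction ->
parametric fitting with AIC/BIC selection -> cohort traces -> base-case
economics -> DSA -> PSA -> CEAC/EVPI -> scenario reruns, writing every
tabular output as CSV plus a machine-readable run manifest.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    build_arm_specs,
    build_settings,
    config_hash,
    get_by_path,
    list_paths,
    set_by_path,
)
from .cohort import build_trace, discount_factor
from .economics import outcomes_table
from .fitting import fit_all, km_estimate, reconstruct_pseudo_ipd
from .simulate import at_risk_counts, digitize, generate_study_ipd
from .uncertainty import (
    ce_plane,
    ceac,
    default_wtp_grid,
    dsa_bounds,
    evaluate_economics,
    evpi,
    run_dsa,
    run_psa,
)

__all__ = [
    "ScenarioSpec",
    "RunManifest",
    "apply_scenario",
    "packaged_scenarios",
    "validate_config",
    "run_full_analysis",
]


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    overrides: Mapping[str, Any] = field(default_factory=dict)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    timestamp: str
    outputs: dict[str, str]  # logical name -> file path
    output_hashes: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def apply_scenario(base_config: Mapping, scenario: ScenarioSpec) -> dict:
    """Deep-copied config with the scenario's overrides applied.

    Unknown paths raise a ``KeyError`` listing valid leaf paths.
    """
    cfg = copy.deepcopy(dict(base_config))
    for path, value in scenario.overrides.items():
        try:
            set_by_path(cfg, path, value)
        except KeyError:
            valid = "\n  ".join(list_paths(cfg))
            raise KeyError(f"unknown config path {path!r}; valid paths:\n  {valid}") from None
    return cfg


def _reprice(path_stem: str, new_base: float) -> dict[str, float]:
    low, high = dsa_bounds(new_base)
    return {f"{path_stem}.base": new_base, f"{path_stem}.low": low, f"{path_stem}.high": high}


def packaged_scenarios(base_config: Mapping) -> dict[str, ScenarioSpec]:
    """The three shipped scenarios (plus the literal-table variant of 2)."""
    laz_base = get_by_path(base_config, "drug_prices.lazertinib.base")
    scen: dict[str, ScenarioSpec] = {}
    scen["scenario1_osimertinib_insurance_price"] = ScenarioSpec(
        "scenario1_osimertinib_insurance_price", _reprice("drug_prices.osimertinib", 509.11)
    )
    scen["scenario2_lazertinib_plus_50pct"] = ScenarioSpec(
        "scenario2_lazertinib_plus_50pct", _reprice("drug_prices.lazertinib", laz_base * 1.5)
    )
    scen["scenario2_table_value"] = ScenarioSpec(
        "scenario2_table_value", _reprice("drug_prices.lazertinib", 5840.10)
    )
    scen["scenario3_alternative_utilities"] = ScenarioSpec(
        "scenario3_alternative_utilities",
        {**_reprice("utilities.pfs", 0.804), **_reprice("utilities.pd", 0.321)},
    )
    return scen


def validate_config(config: Mapping) -> list[str]:
    """Machine-readable list of invariant violations (empty = valid)."""
    errors: list[str] = []

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    try:
        u_pfs = get_by_path(config, "utilities.pfs.base")
        u_pd = get_by_path(config, "utilities.pd.base")
        check(0 <= u_pd <= u_pfs <= 1, "utilities: need 0 <= utilities.pd.base <= utilities.pfs.base <= 1")
    except KeyError as exc:
        errors.append(str(exc))
    for section in ("drug_prices", "monitoring", "adverse_events"):
        for path in list_paths(config.get(section, {}), section):
            if path.endswith((".base", ".low", ".high")) and "disutility" not in path:
                val = get_by_path(config, path)
                check(val >= 0, f"{path}: cost must be >= 0, got {val}")
    for strat, incid in config.get("ae_incidence", {}).items():
        for ae, p in incid.items():
            check(0 <= p <= 1, f"ae_incidence.{strat}.{ae}: incidence must be in [0, 1]")
            check(ae in config.get("adverse_events", {}), f"ae_incidence.{strat}.{ae}: unknown adverse event")
    try:
        rate = get_by_path(config, "settings.annual_discount_rate.base")
        check(0 <= rate <= 0.05, "settings.annual_discount_rate.base outside the standard 0-5% range")
        check(get_by_path(config, "settings.cycle_length_days") > 0, "cycle length must be > 0")
        check(get_by_path(config, "settings.horizon_years") > 0, "horizon must be > 0")
    except KeyError as exc:
        errors.append(str(exc))
    for w in config.get("wtp", {}).get("thresholds", []):
        check(w > 0, f"wtp threshold {w} must be positive")
    for strat, spec in config.get("strategies", {}).items():
        for d in spec.get("drugs", []):
            check(d in config.get("drug_prices", {}), f"strategies.{strat}: unknown drug {d!r}")
        check(spec.get("arm") in config.get("synthetic", {}).get("arms", {}),
              f"strategies.{strat}: unknown arm {spec.get('arm')!r}")
    check(config.get("comparator") in config.get("strategies", {}), "comparator is not a strategy")
    return errors


class ConfigError(ValueError):
    pass


def _fit_selected_models(config, ipd, criterion):
    """Digitize each arm/endpoint KM curve, reconstruct pseudo-IPD, fit and select."""
    dig = config["synthetic"]["digitize"]
    models: dict[str, dict[str, Any]] = {}
    reports: list[pd.DataFrame] = []
    curves: dict[tuple[str, str], Any] = {}
    for (arm, endpoint), sub in ipd.groupby(["arm", "endpoint"], sort=True):
        km = km_estimate(sub)
        curve = digitize(km, dig["grid_spacing"], dig["jitter_sd"], endpoint=endpoint, arm=arm)
        grid = np.arange(0.0, km.max_time + dig["at_risk_spacing"], dig["at_risk_spacing"])
        risk = at_risk_counts(sub, grid)
        pseudo = reconstruct_pseudo_ipd(curve, risk)
        report = fit_all(pseudo, criterion=criterion)
        frame = report.to_frame()
        frame.insert(0, "endpoint", endpoint)
        frame.insert(0, "arm", arm)
        reports.append(frame)
        models.setdefault(arm, {})[endpoint] = report.selected
        curves[(arm, endpoint)] = curve
    return models, pd.concat(reports, ignore_index=True), curves


def _build_traces(config, models, settings):
    traces = {}
    for strat, spec in config["strategies"].items():
        arm = spec["arm"]
        traces[strat] = build_trace(models[arm]["PFS"], models[arm]["OS"], settings)
    return traces


def run_full_analysis(
    config: Mapping,
    seed: int,
    outdir: str | Path,
    n_psa: int | None = None,
    criterion: str | None = None,
    with_scenarios: bool = True,
    with_plots: bool = False,
) -> RunManifest:
    """Execute every stage of the analysis and write the output bundle."""
    errors = validate_config(config)
    if errors:
        raise ConfigError("invalid configuration:\n" + "\n".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    seq = np.random.SeedSequence(seed)
    gen_seed, psa_seed = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2))

    settings = build_settings(config)
    criterion = criterion or config["fitting"]["criterion"]
    comparator = config["comparator"]
    wtp_hi = config["wtp"]["thresholds"][-1]

    # synthetic evidence base
    ipd = generate_study_ipd(build_arm_specs(config), gen_seed)
    outputs["ipd"] = outdir / "ipd.csv"
    ipd.to_csv(outputs["ipd"], index=False)

    # survival fitting
    models, fit_report, curves = _fit_selected_models(config, ipd, criterion)
    outputs["fit_report"] = outdir / "fit_report.csv"
    fit_report.to_csv(outputs["fit_report"], index=False)
    for (arm, endpoint), curve in curves.items():
        key = f"curve_{arm}_{endpoint.lower()}"
        outputs[key] = outdir / f"{key}.csv"
        curve.to_frame().to_csv(outputs[key], index=False)

    # cohort traces
    traces = _build_traces(config, models, settings)
    for strat, trace in traces.items():
        df = trace.df.copy()
        df["discount_factor"] = discount_factor(df["cycle"].to_numpy(), settings)
        outputs[f"trace_{strat}"] = outdir / f"trace_{strat}.csv"
        df.to_csv(outputs[f"trace_{strat}"], index=False)

    # base case
    outcomes = evaluate_economics(config, traces)
    base_table = outcomes_table(outcomes, comparator, wtp_hi)
    outputs["base_case"] = outdir / "base_case.csv"
    base_table.to_csv(outputs["base_case"], index=False)

    # uncertainty
    for strat in config["strategies"]:
        if strat == comparator:
            continue
        tornado = run_dsa(config, traces, intervention=strat, comparator=comparator)
        key = f"tornado_{strat}"
        outputs[key] = outdir / f"{key}.csv"
        tornado.to_csv(outputs[key], index=False)

    psa = run_psa(config, traces, n_iter=n_psa, seed=psa_seed)
    wtp_grid = default_wtp_grid(config)
    outputs["ceac"] = outdir / "ceac.csv"
    ceac(psa, wtp_grid).to_csv(outputs["ceac"], index=False)
    evpi_grid = np.linspace(0.0, config["wtp"]["evpi_max"], config["wtp"]["grid_points"])
    outputs["evpi"] = outdir / "evpi.csv"
    evpi(psa, evpi_grid).to_csv(outputs["evpi"], index=False)
    for strat in config["strategies"]:
        if strat == comparator:
            continue
        key = f"ce_plane_{strat}"
        outputs[key] = outdir / f"{key}.csv"
        ce_plane(psa, strat, comparator).to_csv(outputs[key], index=False)

    if with_plots:
        from . import plots

        ceac_df = pd.read_csv(outputs["ceac"])
        evpi_df = pd.read_csv(outputs["evpi"])
        outputs["ceac_png"] = plots.plot_ceac(ceac_df, outdir / "ceac.png")
        outputs["evpi_png"] = plots.plot_evpi(evpi_df, outdir / "evpi.png")
        for strat in config["strategies"]:
            if strat == comparator:
                continue
            tor = pd.read_csv(outputs[f"tornado_{strat}"])
            outputs[f"tornado_{strat}_png"] = plots.plot_tornado(tor, outdir / f"tornado_{strat}.png")
            plane = pd.read_csv(outputs[f"ce_plane_{strat}"])
            outputs[f"ce_plane_{strat}_png"] = plots.plot_ce_plane(
                plane, outdir / f"ce_plane_{strat}.png", wtp=wtp_hi
            )

    # scenarios (survival curves unchanged; economics re-evaluated)
    if with_scenarios:
        for name, scen in packaged_scenarios(config).items():
            cfg = apply_scenario(config, scen)
            table = outcomes_table(
                evaluate_economics(cfg, traces), comparator, cfg["wtp"]["thresholds"][-1]
            )
            outputs[name] = outdir / f"{name}.csv"
            table.to_csv(outputs[name], index=False)

    hashes = {
        key: hashlib.sha256(path.read_bytes()).hexdigest() for key, path in outputs.items()
    }
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs={k: str(v) for k, v in outputs.items()},
        output_hashes=hashes,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
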