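"""DSA bounds, distribution moments, PSA, CEAC and EVPI."""

import numpy as np
import pandas as pd
import pytest

from survecon.cohort import ModelSettings, build_trace
from survecon.uncertainty import (
    ParameterDistribution,
    PSAResult,
    build_parameters,
    ce_plane,
    ceac,
    dsa_bounds,
    evaluate_economics,
    evpi,
    moments_to_sampler,
    run_dsa,
    run_psa,
)

from conftest import make_model


# ------------------------------------------------------------ DSA bounds


def test_default_bounds_are_plus_minus_20_percent():
    lo, hi = dsa_bounds(12_623.80)
    assert lo == pytest.approx(10_099.04)
    assert hi == pytest.approx(15_148.56)


def test_bounds_pass_through_and_zero_base():
    assert dsa_bounds(5.0, 1.0, 9.0) == (1.0, 9.0)
    assert dsa_bounds(0.0) == (0.0, 0.0)


def test_utility_bound_capped_at_one():
    lo, hi = dsa_bounds(0.9, cap=1.0)
    assert hi == 1.0 and lo == pytest.approx(0.72)


def test_inverted_bounds_rejected():
    with pytest.raises(ValueError):
        dsa_bounds(5.0, 9.0, 1.0)


# ---------------------------------------------------- moment matching


def test_beta_moments_for_pfs_utility():
    """Utility 0.71, range (0.57, 0.85): sd 0.0714, alpha 27.95, beta 11.41."""
    p = ParameterDistribution("u_pfs", "utilities.pfs.base", 0.71, 0.57, 0.85, "beta")
    sd = (0.85 - 0.57) / (2 * 1.959963984540054)
    assert sd == pytest.approx(0.0714, abs=2e-4)
    common = 0.71 * 0.29 / sd**2 - 1
    assert 0.71 * common == pytest.approx(27.95, abs=0.05)
    assert 0.29 * common == pytest.approx(11.41, abs=0.05)
    draws = moments_to_sampler(p)(np.random.default_rng(0), 100_000)
    assert draws.mean() == pytest.approx(0.71, abs=0.002)
    assert np.all((draws > 0) & (draws < 1))


def test_gamma_moments_for_drug_cost():
    p = ParameterDistribution(
        "osi", "drug_prices.osimertinib.base", 12_623.80, 10_099.04, 15_148.56, "gamma"
    )
    sd = (15_148.56 - 10_099.04) / (2 * 1.959963984540054)
    assert (12_623.80 / sd) ** 2 == pytest.approx(96.04, abs=0.05)
    draws = moments_to_sampler(p)(np.random.default_rng(1), 100_000)
    assert draws.mean() == pytest.approx(12_623.80, rel=0.005)
    assert np.all(draws > 0)


def test_degenerate_range_is_point_mass():
    p = ParameterDistribution("x", "end_of_life.base", 7.0, 7.0, 7.0, "gamma")
    draws = moments_to_sampler(p)(np.random.default_rng(2), 50)
    assert np.all(draws == 7.0)


def test_infeasible_beta_falls_back_to_uniform():
    class Wider:  # duck-typed: a range so wide the beta variance is infeasible
        name, path, base, low, high, family = "w", "p", 0.5, -1.4, 2.4, "beta"

    with pytest.warns(UserWarning, match="infeasible"):
        draws = moments_to_sampler(Wider)(np.random.default_rng(3), 1000)
    assert np.all((draws >= Wider.low) & (draws <= Wider.high))


# --------------------------------------------------------- DSA / PSA


def _toy_problem(config):
    """Fixed traces: the combination strategy gets slower progression so its
    incremental QALYs vs the comparator are positive."""
    settings = ModelSettings()
    better = build_trace(
        make_model("exponential", 1.0, 26.0), make_model("exponential", 1.0, 36.0), settings
    )
    proxy = build_trace(
        make_model("exponential", 1.0, 18.0), make_model("exponential", 1.0, 30.0), settings
    )
    return {
        name: (better if name == "amivantamab_lazertinib" else proxy)
        for name in config["strategies"]
    }


def test_dsa_zero_effect_parameter_has_zero_spread(config):
    traces = _toy_problem(config)
    null = ParameterDistribution(
        "AE cost: alt_ast_increase", "adverse_events.alt_ast_increase.cost.base", 0.0, 0.0, 0.0, "gamma"
    )
    out = run_dsa(config, traces, "amivantamab_lazertinib", parameters=[null])
    assert out["spread"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_dsa_direction_comparator_price(config):
    """Raising the comparator's drug price lowers the intervention's ICER."""
    traces = _toy_problem(config)
    p = ParameterDistribution(
        "Drug cost: osimertinib",
        "drug_prices.osimertinib.base",
        12_623.80,
        10_099.04,
        15_148.56,
        "gamma",
    )
    out = run_dsa(config, traces, "amivantamab_lazertinib", parameters=[p])
    assert out["icer_at_high"].iloc[0] < out["icer_at_low"].iloc[0]


def test_dsa_two_cycle_hand_model(config):
    """Drug-price-only toy: the ICER at each bound equals the hand formula."""
    traces = _toy_problem(config)
    trace = traces["amivantamab_lazertinib"]  # amivantamab accrues on this trace
    settings = ModelSettings()
    from survecon.cohort import discount_factor
    from survecon.economics import _cycle_occupancy

    occ = _cycle_occupancy(trace.pfs, settings)
    w = discount_factor(np.arange(len(occ)), settings)
    pfs_weight = float((occ * w).sum())
    p = ParameterDistribution(
        "Drug cost: amivantamab",
        "drug_prices.amivantamab.base",
        17_418.13,
        13_982.50,
        20_973.75,
        "gamma",
    )
    out = run_dsa(config, traces, "amivantamab_lazertinib", parameters=[p])
    base = evaluate_economics(config, traces)
    dq = base["amivantamab_lazertinib"].qalys - base["osimertinib"].qalys
    dc = base["amivantamab_lazertinib"].total_cost - base["osimertinib"].total_cost
    for side, bound in (("icer_at_low", 13_982.50), ("icer_at_high", 20_973.75)):
        expected = (dc + (bound - 17_418.13) * pfs_weight) / dq
        assert out[side].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_psa_seed_determinism(config):
    traces = _toy_problem(config)
    a = run_psa(config, traces, n_iter=20, seed=5)
    b = run_psa(config, traces, n_iter=20, seed=5)
    pd.testing.assert_frame_equal(a.costs, b.costs)
    pd.testing.assert_frame_equal(a.draws, b.draws)


def test_psa_degenerate_distributions_reproduce_base_case(config):
    traces = _toy_problem(config)
    params = [
        ParameterDistribution(p.name, p.path, p.base, p.base, p.base, p.family)
        for p in build_parameters(config)
    ]
    psa = run_psa(config, traces, n_iter=3, seed=9, parameters=params)
    base = evaluate_economics(config, traces)
    for strat, out in base.items():
        assert np.all(psa.costs[strat].to_numpy() == out.total_cost)
        assert np.all(psa.qalys[strat].to_numpy() == out.qalys)


def test_psa_mean_cost_near_base_case(config):
    """Costs are linear in the sampled parameters, so the PSA mean tracks base."""
    traces = _toy_problem(config)
    psa = run_psa(config, traces, n_iter=2000, seed=3)
    base = evaluate_economics(config, traces)
    for strat in psa.strategies:
        assert psa.costs[strat].mean() == pytest.approx(base[strat].total_cost, rel=0.02)


# --------------------------------------------------------- CEAC / EVPI


def _psa_from(costs, qalys, names):
    return PSAResult(
        draws=pd.DataFrame(index=range(len(costs))),
        costs=pd.DataFrame(costs, columns=names),
        qalys=pd.DataFrame(qalys, columns=names),
        seed=0,
    )


def test_ceac_dominant_strategy_has_probability_one():
    psa = _psa_from([[1.0, 5.0]] * 4, [[2.0, 1.0]] * 4, ["a", "b"])
    out = ceac(psa, [0.0, 10.0, 100.0])
    assert np.all(out["a"].to_numpy() == 1.0)
    assert np.all(out["b"].to_numpy() == 0.0)


def test_ceac_matches_enumeration_on_four_draws():
    """Brute-force count over 4 hand-made draws and 2 strategies."""
    costs = [[10.0, 0.0], [0.0, 10.0], [5.0, 5.0], [2.0, 1.0]]
    qalys = [[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 0.0]]
    psa = _psa_from(costs, qalys, ["a", "b"])
    out = ceac(psa, [20.0])
    # NMB at wtp 20: a: [10, -0, 15, -2]; b: [0, 10, -5, -1] -> a wins draws 1,3; b wins 2,4
    assert out.loc[0, "a"] == pytest.approx(0.5)
    assert out.loc[0, "b"] == pytest.approx(0.5)


def test_ceac_tie_goes_to_cheaper_strategy():
    psa = _psa_from([[5.0, 3.0]], [[1.0, 1.0]], ["pricey", "cheap"])
    out = ceac(psa, [0.0, 50.0])
    assert np.all(out["cheap"].to_numpy() == 1.0)


def test_ceac_partition_of_unity(config):
    traces = _toy_problem(config)
    psa = run_psa(config, traces, n_iter=100, seed=11)
    grid = np.linspace(0, 300_000, 31)
    out = ceac(psa, grid)
    sums = out[psa.strategies].sum(axis=1).to_numpy()
    assert sums == pytest.approx(np.ones_like(sums), abs=1e-12)


def test_evpi_zero_when_one_strategy_always_optimal():
    psa = _psa_from([[1.0, 5.0]] * 5, [[2.0, 1.0]] * 5, ["a", "b"])
    assert np.all(evpi(psa, [0.0, 10.0])["evpi"].to_numpy() == 0.0)


def test_evpi_hand_enumeration_two_draws():
    """NMBs {(1,0),(0,1)}: E[max] = 1, max E = 0.5, EVPI = 0.5."""
    psa = _psa_from([[-1.0, 0.0], [0.0, -1.0]], [[0.0, 0.0], [0.0, 0.0]], ["a", "b"])
    assert evpi(psa, [0.0])["evpi"].iloc[0] == pytest.approx(0.5)


def test_evpi_non_negative_everywhere(config):
    traces = _toy_problem(config)
    psa = run_psa(config, traces, n_iter=100, seed=13)
    out = evpi(psa, np.linspace(0, 300_000, 31))
    assert (out["evpi"] >= 0).all()


def test_ce_plane_increments(config):
    traces = _toy_problem(config)
    psa = run_psa(config, traces, n_iter=10, seed=1)
    plane = ce_plane(psa, "amivantamab_lazertinib", "osimertinib")
    manual = psa.costs["amivantamab_lazertinib"] - psa.costs["osimertinib"]
    pd.testing.assert_series_equal(
        plane["incremental_cost"], manual, check_names=False
    )
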