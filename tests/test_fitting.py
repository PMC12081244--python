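"""KM estimation, pseudo-IPD reconstruction, parametric MLE and selection."""

import numpy as np
import pandas as pd
import pytest

from survecon import distributions as dist
from survecon.fitting import (
    FitReport,
    ParametricSurvivalModel,
    cox_hazard_ratio,
    fit_all,
    fit_family,
    km_estimate,
    median_survival,
    reconstruct_pseudo_ipd,
    select_model,
    survival_at,
)
from survecon.simulate import ArmSpec, at_risk_counts, digitize, generate_arm_ipd

from conftest import make_model


# ---------------------------------------------------------------- KM


def test_km_hand_computed_all_events(three_event_ipd):
    km = km_estimate(three_event_ipd)
    assert km.evaluate([1.0, 2.0, 3.0]) == pytest.approx([2 / 3, 1 / 3, 0.0])
    assert km.evaluate(0.0) == 1.0


def test_km_with_censoring_shrinks_risk_set():
    ipd = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 0, 1]})
    km = km_estimate(ipd)
    assert km.evaluate(1.0) == pytest.approx(2 / 3)
    assert km.evaluate(3.0) == pytest.approx(0.0)


def test_km_single_censored_observation_is_flat():
    km = km_estimate(pd.DataFrame({"time_months": [5.0], "event": [0]}))
    assert np.all(km.survival == 1.0)
    assert km.median == np.inf


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        km_estimate(pd.DataFrame({"time_months": [], "event": []}))


# ------------------------------------------------- reconstruction


def test_reconstruction_recovers_three_patient_curve(three_event_ipd):
    km = km_estimate(three_event_ipd)
    curve = digitize(km, 0.5, endpoint="PFS", arm="x")
    risk = at_risk_counts(three_event_ipd, [0.0, 1.0, 2.0, 3.0])
    rec = reconstruct_pseudo_ipd(curve, risk)
    assert sorted(rec["time_months"].tolist()) == pytest.approx([1.0, 2.0, 3.0])
    assert (rec["event"] == 1).all()


def test_reconstruction_flat_curve_all_censored():
    curve = type("C", (), {})()
    curve.times = np.array([0.0, 5.0, 10.0])
    curve.survival = np.array([1.0, 1.0, 1.0])
    curve.arm = curve.endpoint = ""
    curve.at_risk = None
    risk = pd.DataFrame({"time_months": [0.0, 10.0], "n_at_risk": [50, 50]})
    rec = reconstruct_pseudo_ipd(curve, risk)
    assert len(rec) == 50
    assert (rec["event"] == 0).all()


def test_reconstruction_round_trip_sup_norm():
    """Noiseless digitization of a 200-patient arm reconstructs within 0.02."""
    spec = ArmSpec(
        name="a",
        pfs_family="weibull",
        pfs_params={"shape": 1.2, "scale": 20.0},
        n_patients=200,
        admin_censor_time=40.0,
    )
    pfs = generate_arm_ipd(spec, 3).query("endpoint == 'PFS'")
    km = km_estimate(pfs)
    curve = digitize(km, 1.0, endpoint="PFS", arm="a")
    risk = at_risk_counts(pfs, np.arange(0.0, km.max_time + 3.0, 3.0))
    rec = reconstruct_pseudo_ipd(curve, risk)
    km2 = km_estimate(rec)
    assert np.max(np.abs(km2.evaluate(curve.times) - curve.survival)) <= 0.02


def test_reconstruction_without_at_risk_warns(three_event_ipd, caplog):
    km = km_estimate(three_event_ipd)
    curve = digitize(km, 0.5)
    with caplog.at_level("WARNING"):
        rec = reconstruct_pseudo_ipd(curve, None, n_start=3)
    assert "event-only" in caplog.text
    assert len(rec) == 3


def test_reconstruction_rejects_rising_curve():
    curve = type("C", (), {})()
    curve.times = np.array([0.0, 1.0, 2.0])
    curve.survival = np.array([1.0, 0.5, 0.9])
    curve.arm = curve.endpoint = ""
    curve.at_risk = None
    with pytest.raises(ValueError):
        reconstruct_pseudo_ipd(curve, pd.DataFrame({"time_months": [0, 2], "n_at_risk": [10, 5]}))


# ------------------------------------------------------------ MLE


def test_exponential_mle_closed_form_all_events(three_event_ipd):
    m = fit_family(three_event_ipd, "exponential")
    assert 1 / m.scale == pytest.approx(3 / 6, rel=1e-6)  # rate = events / total time


def test_exponential_mle_closed_form_with_censoring():
    ipd = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 0, 1]})
    m = fit_family(ipd, "exponential")
    assert 1 / m.scale == pytest.approx(2 / 6, rel=1e-6)


def test_numeric_optimizer_matches_closed_form_on_censored_sample(rng):
    """Independent oracle: exponential MLE has the closed form sum(t)/sum(e)."""
    t = rng.exponential(15.0, 400)
    c = rng.exponential(25.0, 400)
    obs, ev = np.minimum(t, c), (t <= c).astype(int)
    m = fit_family(pd.DataFrame({"time_months": obs, "event": ev}), "exponential")
    assert m.scale == pytest.approx(obs.sum() / ev.sum(), rel=1e-6)


def test_weibull_parameter_recovery():
    x = dist.rvs("weibull", 1.3, 30.0, 10_000, np.random.default_rng(11))
    m = fit_family(pd.DataFrame({"time_months": x, "event": 1}), "weibull")
    assert m.shape == pytest.approx(1.3, rel=0.05)
    assert m.scale == pytest.approx(30.0, rel=0.05)


def test_weibull_loglik_dominates_exponential():
    """Nesting: the exponential is a Weibull submodel."""
    x = dist.rvs("gamma", 2.0, 10.0, 2_000, np.random.default_rng(8))
    ipd = pd.DataFrame({"time_months": x, "event": 1})
    mw = fit_family(ipd, "weibull")
    me = fit_family(ipd, "exponential")
    assert mw.loglik >= me.loglik - 1e-6


def test_information_criteria_recomputable():
    x = dist.rvs("lognormal", 0.8, 20.0, 500, np.random.default_rng(3))
    ipd = pd.DataFrame({"time_months": x, "event": 1})
    for fam in ("exponential", "weibull", "lognormal"):
        m = fit_family(ipd, fam)
        k = 1 if fam == "exponential" else 2
        assert m.aic == pytest.approx(2 * k - 2 * m.loglik, abs=1e-9)
        assert m.bic == pytest.approx(k * np.log(m.n_obs) - 2 * m.loglik, abs=1e-9)


def test_fit_preconditions():
    with pytest.raises(ValueError):
        fit_family(pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0]}), "exponential")
    with pytest.raises(ValueError):
        fit_family(pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 0, 0]}), "weibull")
    with pytest.raises(ValueError):
        fit_family(pd.DataFrame({"time_months": [2.0] * 5, "event": [1] * 5}), "exponential")


# ------------------------------------------------------ selection


def test_select_model_is_brute_force_argmin():
    x = dist.rvs("weibull", 1.5, 20.0, 1_000, np.random.default_rng(6))
    report = fit_all(pd.DataFrame({"time_months": x, "event": 1}), criterion="aic")
    brute = min(
        (m for m in report.models.values() if m.converged), key=lambda m: m.aic
    ).family
    assert report.selected_family == brute


def test_select_model_single_candidate():
    m = make_model("gamma", 2.0, 5.0)
    m.aic = m.bic = 100.0
    assert select_model({"gamma": m}) == "gamma"


def test_select_model_tie_goes_to_earlier_family():
    models = {}
    for fam, aic in (("exponential", 100.0), ("weibull", 98.0), ("gompertz", 98.0)):
        m = make_model(fam, 1.0, 10.0)
        m.aic = aic
        models[fam] = m
    assert select_model(models, "aic") == "weibull"


def test_select_model_ignores_unconverged_and_needs_one_fit():
    bad = make_model("weibull", 1.0, 5.0)
    bad.converged = False
    with pytest.raises(ValueError):
        select_model({"weibull": bad})


def test_bic_prefers_exponential_on_exponential_data():
    wins = 0
    for s in range(10):
        x = dist.rvs("exponential", 1.0, 15.0, 2_000, np.random.default_rng(100 + s))
        rep = fit_all(pd.DataFrame({"time_months": x, "event": 1}), criterion="bic")
        wins += rep.selected_family == "exponential"
    assert wins >= 9


# ----------------------------------------------- queries and Cox


def test_survival_and_median_queries():
    m = make_model("exponential", 1.0, 20.0)
    assert survival_at(m, 0.0) == pytest.approx(1.0)
    assert median_survival(m) == pytest.approx(20 * np.log(2), rel=1e-9)
    m2 = make_model("loglogistic", 2.5, 23.7)
    assert median_survival(m2) == pytest.approx(23.7, rel=1e-9)
    with pytest.raises(ValueError):
        survival_at(m, -1.0)


def test_cox_recovers_weibull_ph_hazard_ratio():
    """Proportional-hazards Weibull pair with rate ratio 0.7."""
    shape = 1.2
    s0, hr = 20.0, 0.7
    s1 = s0 * hr ** (-1 / shape)
    frames = []
    for seed, (name, scale) in enumerate((("treat", s1), ("control", s0))):
        x = dist.rvs("weibull", shape, scale, 3_000, np.random.default_rng(seed))
        frames.append(pd.DataFrame({"time_months": x, "event": 1, "arm": name, "endpoint": "PFS"}))
    est = cox_hazard_ratio(pd.concat(frames), reference_arm="control")
    assert est == pytest.approx(0.7, abs=0.05)
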