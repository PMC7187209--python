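"""Survival-model unit tests: product-limit estimator, Cox engine against
independent oracles, multilevel fit, and the Weibull parametric fit."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from kmpool import (
    CoxConvergenceError,
    PooledComparisonSpec,
    cox_fit,
    km_estimate,
    multilevel_cox_fit,
    pooled_comparison,
    simulate_trial_ipd,
    trial_preset,
    weibull_ph_fit,
)
from kmpool.simulate import TrialSimConfig


# ---------------------------------------------------------------------------
# independent oracle: explicit Efron partial likelihood, term by term
# ---------------------------------------------------------------------------


def naive_efron_score(beta, time, event, x):
    """Score and Hessian of the Efron partial likelihood via explicit loops."""
    score = 0.0
    hess = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        m = len(deaths)
        s0D = sum(np.exp(beta * x[i]) for i in deaths)
        s1D = sum(np.exp(beta * x[i]) * x[i] for i in deaths)
        s2D = sum(np.exp(beta * x[i]) * x[i] ** 2 for i in deaths)
        R0 = sum(np.exp(beta * x[i]) for i in risk)
        R1 = sum(np.exp(beta * x[i]) * x[i] for i in risk)
        R2 = sum(np.exp(beta * x[i]) * x[i] ** 2 for i in risk)
        score += sum(x[i] for i in deaths)
        for ell in range(m):
            f = ell / m
            d0 = R0 - f * s0D
            d1 = R1 - f * s1D
            d2 = R2 - f * s2D
            score -= d1 / d0
            hess -= d2 / d0 - (d1 / d0) ** 2
    return score, hess


def naive_newton_beta(time, event, x, tol=1e-12):
    beta = 0.0
    for _ in range(60):
        g, h = naive_efron_score(beta, time, event, x)
        if abs(g) < tol:
            break
        beta -= g / h
    return beta


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_hand_product_limit():
    """S after events at 1, 3, 4 with a censoring at 2: 0.75, 0.375, 0."""
    curve = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
    assert curve.survival_at(1) == pytest.approx(0.75)
    assert curve.survival_at(3) == pytest.approx(0.375)
    assert curve.survival_at(4) == pytest.approx(0.0)
    assert curve.variance_at(0) == 0.0
    assert np.all(np.isfinite(curve.survival)) and np.all(np.isfinite(curve.variance))


def test_km_no_events_is_flat():
    curve = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
    assert np.all(curve.survival == 1.0)
    assert curve.events == 0


def test_km_monotone_and_bounded():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 200)
    e = rng.integers(0, 2, 200)
    curve = km_estimate(t, e)
    assert np.all(np.diff(curve.survival) <= 1e-15)
    assert curve.survival.min() >= 0 and curve.survival.max() <= 1


# ---------------------------------------------------------------------------
# Cox engine
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fixture_name", ["small_ipd", "tied_ipd"])
def test_cox_matches_bruteforce_newton(fixture_name, request):
    """Engine beta equals an explicit term-by-term partial-likelihood
    maximization to 1e-8, and the oracle score at beta-hat is < 1e-6."""
    df = request.getfixturevalue(fixture_name)
    t = df["time"].to_numpy()
    e = df["event"].to_numpy(dtype=int)
    x = df["treat"].to_numpy()
    fit = cox_fit(t, e, x)
    beta_oracle = naive_newton_beta(t, e, x)
    assert fit.log_hr == pytest.approx(beta_oracle, abs=1e-8)
    g, h = naive_efron_score(fit.log_hr, t, e, x)
    assert abs(g) < 1e-6
    assert fit.se == pytest.approx(np.sqrt(-1.0 / h), rel=1e-6)


def test_cox_matches_lifelines():
    rng = np.random.default_rng(3)
    n = 800
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.01 * np.exp(-0.3 * x)))
    c = np.minimum(rng.exponential(90, n), 100)
    time, event = np.minimum(t, c), (t <= c).astype(int)
    fit = cox_fit(time, event, x)
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e")
    assert fit.log_hr == pytest.approx(float(cph.params_["x"]), abs=1e-6)
    assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)


def test_identical_arms_give_zero_effect():
    """Duplicating one arm's outcomes under both labels forces beta = 0."""
    t = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
    e = np.tile([1, 0, 1, 1, 0], 2)
    x = np.repeat([0.0, 1.0], 5)
    fit = cox_fit(t, e, x)
    assert fit.log_hr == 0.0


def test_rank_invariance_under_time_rescaling():
    """The partial likelihood depends on times only through ranks."""
    rng = np.random.default_rng(8)
    t = rng.exponential(50, 300)
    e = rng.integers(0, 2, 300)
    x = rng.integers(0, 2, 300).astype(float)
    a = cox_fit(t, e, x)
    b = cox_fit(t / 12.0, e, x)  # months -> years
    assert a.log_hr == pytest.approx(b.log_hr, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_breslow_differs_from_efron_on_ties(tied_ipd):
    ef = cox_fit(tied_ipd["time"], tied_ipd["event"], tied_ipd["treat"], ties="efron")
    br = cox_fit(tied_ipd["time"], tied_ipd["event"], tied_ipd["treat"], ties="breslow")
    assert ef.log_hr != br.log_hr  # tie corrections genuinely applied
    with pytest.raises(ValueError):
        cox_fit(tied_ipd["time"], tied_ipd["event"], tied_ipd["treat"], ties="exact")


def test_monotone_likelihood_raises_diagnostic():
    """All treated events precede all control events: beta diverges."""
    t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    e = np.ones(6, dtype=int)
    x = np.array([1.0, 1, 1, 0, 0, 0])
    with pytest.raises(CoxConvergenceError, match="separat|diverg"):
        cox_fit(t, e, x)


def test_cox_requires_events_and_varying_treatment():
    with pytest.raises(ValueError, match="event"):
        cox_fit([1.0, 2.0], [0, 0], [0.0, 1.0])
    with pytest.raises(ValueError, match="vary"):
        cox_fit([1.0, 2.0], [1, 1], [1.0, 1.0])


def test_wald_ci_brackets_hr(small_ipd):
    fit = cox_fit(small_ipd["time"], small_ipd["event"], small_ipd["treat"])
    lo, hi = fit.ci
    assert lo < fit.hr < hi
    assert 0 < fit.p_value <= 1


# ---------------------------------------------------------------------------
# multilevel (frailty) fit
# ---------------------------------------------------------------------------


def test_frailty_tau_zero_reduces_to_plain():
    ipd = simulate_trial_ipd(trial_preset("monotherapy-vs-control", seed=3))
    args = (
        ipd["time_months"].to_numpy(),
        ipd["event"].to_numpy(),
        (ipd["arm"] == "mono").to_numpy(float),
    )
    plain = cox_fit(*args)
    frail = multilevel_cox_fit(*args, group=ipd["trial_id"].to_numpy(), tau2=0.0)
    assert frail.log_hr == pytest.approx(plain.log_hr, abs=1e-6)
    assert frail.se == pytest.approx(plain.se, abs=1e-6)
    assert frail.tau2 == 0.0


def test_frailty_single_group_warns_and_falls_back():
    cfg = TrialSimConfig(n_per_arm=150, n_trials=1, censor_rate=0.002, seed=1)
    ipd = simulate_trial_ipd(cfg)
    args = (
        ipd["time_months"].to_numpy(),
        ipd["event"].to_numpy(),
        (ipd["arm"] == "mono").to_numpy(float),
    )
    with pytest.warns(UserWarning, match="fewer than 2 groups"):
        frail = multilevel_cox_fit(*args, group=ipd["trial_id"].to_numpy())
    assert frail.tau2 == 0.0
    assert frail.log_hr == pytest.approx(cox_fit(*args).log_hr, abs=1e-12)


def test_frailty_matches_r_coxph_gaussian(tmp_path):
    """Independent oracle: R survival's coxph with gaussian frailty."""
    cfg = trial_preset(
        "monotherapy-vs-control", seed=9, n_per_arm=[(200, 200)] * 7, trial_effect_sd=0.3
    )
    ipd = simulate_trial_ipd(cfg).assign(treat=lambda d: (d["arm"] == "mono").astype(int))
    csv = tmp_path / "ipd.csv"
    ipd.to_csv(csv, index=False)
    fit = multilevel_cox_fit(
        ipd["time_months"].to_numpy(),
        ipd["event"].to_numpy(),
        ipd["treat"].to_numpy(float),
        group=ipd["trial_id"].to_numpy(),
    )
    script = (
        f'd <- read.csv("{csv}"); suppressMessages(library(survival)); '
        "m <- coxph(Surv(time_months, event) ~ treat + frailty.gaussian(trial_id), data=d); "
        'cat(coef(m)[1], sqrt(m$var[1,1]), "\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300, check=True
    )
    r_beta, r_se = (float(v) for v in out.stdout.split())
    assert fit.log_hr == pytest.approx(r_beta, abs=0.01)
    assert fit.se == pytest.approx(r_se, abs=0.01)


# ---------------------------------------------------------------------------
# pooled comparison plumbing
# ---------------------------------------------------------------------------


def test_pooled_comparison_counts_and_validation():
    ipd = simulate_trial_ipd(trial_preset("monotherapy-vs-control", seed=2))
    trials = sorted(ipd["trial_id"].unique())
    spec = PooledComparisonSpec([(t, "control", "mono") for t in trials])
    fit = pooled_comparison(ipd, spec)
    sizes = ipd.groupby("arm").size()
    assert fit.n_per_arm["control"] == sizes["control"]
    assert fit.n_per_arm["treated"] == sizes["mono"]
    assert fit.events == ipd["event"].sum()
    with pytest.raises(ValueError, match="both"):
        PooledComparisonSpec([("trial_1", "mono", "mono")]).validate()
    with pytest.raises(ValueError, match="no records"):
        pooled_comparison(ipd, PooledComparisonSpec([("trial_1", "control", "combo")]))


# ---------------------------------------------------------------------------
# Weibull proportional hazards
# ---------------------------------------------------------------------------


def test_weibull_exponential_null():
    rng = np.random.default_rng(4)
    n = 10000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(100, n)
    fit = weibull_ph_fit(t, np.ones(n), x)
    assert fit.shape == pytest.approx(1.0, abs=0.05)
    assert fit.log_hr == pytest.approx(0.0, abs=0.06)


def test_weibull_matches_exponential_rate_ratio():
    """Without censoring the exponential MLE of the HR is the ratio of
    events per person-time; the Weibull fit must land on it."""
    rng = np.random.default_rng(5)
    n = 4000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.02 * np.exp(-0.4 * x)))
    fit = weibull_ph_fit(t, np.ones(n), x)
    rate_t = x.sum() / t[x == 1].sum()
    rate_c = (n - x.sum()) / t[x == 0].sum()
    assert np.exp(fit.log_hr) == pytest.approx(rate_t / rate_c, rel=0.01)


def test_weibull_agrees_with_cox_on_weibull_data():
    cfg = TrialSimConfig(
        n_per_arm=2500, n_trials=1, true_log_hr=np.log(0.8), shape=1.4,
        baseline_hazard=0.001, censor_rate=0.002, admin_censor_time=120, seed=6,
    )
    ipd = simulate_trial_ipd(cfg)
    t = ipd["time_months"].to_numpy()
    e = ipd["event"].to_numpy()
    x = (ipd["arm"] == "mono").to_numpy(float)
    wb = weibull_ph_fit(t, e, x)
    cx = cox_fit(t, e, x)
    assert abs(wb.log_hr - cx.log_hr) < 0.02
    assert wb.shape == pytest.approx(1.4, rel=0.1)
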