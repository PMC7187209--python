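"""Propensity-score machinery: logistic model recovery, matching against a
brute-force greedy oracle, weighting and stratification properties, and the
adjusted effect estimates."""

import warnings

import numpy as np
import pandas as pd
import pytest

from kmpool import (
    estimate_effect,
    fit_propensity,
    ipw_weights,
    match_pairs,
    registry_preset,
    simulate_registry,
    standardized_mean_differences,
    stratify,
)
from kmpool.propensity import PropensityModel


def _dummy_model(scores):
    scores = np.asarray(scores, dtype=float)
    logit = np.log(scores / (1 - scores))
    sd = float(np.std(logit, ddof=1)) if scores.size > 1 else 0.0
    return PropensityModel(
        terms=[], coefficients={}, scores=scores, logit_scores=logit,
        sd_logit=sd, aic=np.nan, age_center=70.0,
    )


def _toy_cohort(treated, times=None):
    n = len(treated)
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "age_years": rng.normal(70, 10, n).round(),
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "pt_stage": np.where(rng.random(n) < 0.1, "T4", "T3"),
            "nodes_lt10": rng.integers(0, 2, n),
            "site": np.where(rng.random(n) < 0.6, "right", "left"),
            "diff_poor": rng.integers(0, 2, n),
            "treated": treated,
            "time_months": rng.exponential(60, n) if times is None else times,
            "event": rng.integers(0, 2, n),
        }
    )


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------


def test_propensity_recovers_known_coefficients():
    cfg = registry_preset(seed=1, n=50000)
    co = simulate_registry(cfg)
    model = fit_propensity(co, selection="none")
    # recompute each true coefficient's sampling check: within ~3 SE at this n
    truth = cfg.assignment_coefficients
    fitted = model.coefficients
    assert fitted["pt_t4"] == pytest.approx(truth["pt_t4"], abs=0.25)
    assert fitted["age"] == pytest.approx(truth["age"], abs=0.02)
    assert fitted["nodes_lt10"] == pytest.approx(truth["nodes_lt10"], abs=0.25)
    assert np.all((model.scores > 0) & (model.scores < 1))


def test_propensity_null_assignment_flat_scores():
    zero = {k: 0.0 for k in registry_preset().assignment_coefficients}
    co = simulate_registry(registry_preset(seed=2, n=20000, assignment_coefficients=zero))
    model = fit_propensity(co, selection="aic_backward")
    # backward AIC prunes most noise terms and scores hug the marginal rate
    assert len(model.terms) <= 2
    assert np.std(model.scores) < 0.01
    assert model.scores.mean() == pytest.approx(co["treated"].mean(), abs=0.005)


def test_propensity_requires_both_groups_and_flags_separation():
    co = _toy_cohort(np.zeros(50, dtype=int))
    with pytest.raises(ValueError, match="both treated and untreated"):
        fit_propensity(co)
    co2 = _toy_cohort(np.r_[np.ones(25, int), np.zeros(25, int)])
    co2["pt_stage"] = np.where(co2["treated"] == 1, "T4", "T3")  # separates
    with pytest.raises(ValueError, match="separation.*pt_t4"):
        fit_propensity(co2, selection="none")


def test_propensity_score_overlap_ncr_like(ncr_like_cohort):
    """Treated and control score ranges overlap substantially, mirroring the
    published cohort (control <0.01-0.84, treated 0.01-0.89)."""
    model = fit_propensity(ncr_like_cohort, include_interactions=True)
    s = model.scores
    tr = ncr_like_cohort["treated"].to_numpy() == 1
    lo = max(s[tr].min(), s[~tr].min())
    hi = min(s[tr].max(), s[~tr].max())
    assert hi - lo > 0.3  # wide common support
    assert s[~tr].min() < 0.02 and s[tr].max() > 0.5


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def test_matching_greedy_oracle_example():
    """Treated scores {0.30, 0.20} vs controls {0.29, 0.28, 0.05} with
    caliper 0.05: (0.30, 0.29) pairs, 0.20 is dropped (0.28 taken? no -
    nearest to 0.20 is 0.28 at distance 0.08 > caliper)."""
    treated = np.array([1, 1, 0, 0, 0])
    co = _toy_cohort(treated)
    model = _dummy_model([0.30, 0.20, 0.29, 0.28, 0.05])
    sample = match_pairs(co, model, caliper_rule=0.05)
    assert sample.provenance["n_pairs"] == 1
    assert sample.provenance["n_treated_unmatched"] == 1
    got = set(sample.data["patient_id"])
    assert got == {"p0", "p2"}  # 0.30 matched to 0.29


def test_matching_identical_scores_matches_everyone():
    treated = np.array([1, 1, 0, 0, 0, 0])
    co = _toy_cohort(treated)
    model = _dummy_model(np.full(6, 0.3))
    for rule in ("exact", "0.2sd"):
        sample = match_pairs(co, model, caliper_rule=rule)
        assert sample.provenance["n_pairs"] == 2


def test_matching_invariants_on_cohort(ncr_like_cohort):
    model = fit_propensity(ncr_like_cohort, selection="none")
    sample = match_pairs(ncr_like_cohort, model, caliper_rule="0.2sd")
    data = sample.data
    # pairs disjoint and 1:1
    assert data["patient_id"].is_unique
    per_pair = data.groupby("pair_id")["treated"].agg(["size", "sum"])
    assert (per_pair["size"] == 2).all() and (per_pair["sum"] == 1).all()
    # every pair satisfies its caliper
    ps = pd.Series(model.scores, index=ncr_like_cohort["patient_id"].to_numpy())
    wide = data.pivot_table(index="pair_id", columns="treated", values="patient_id", aggfunc="first")
    gaps = np.abs(ps[wide[1]].to_numpy() - ps[wide[0]].to_numpy())
    assert np.all(gaps <= sample.provenance["caliper"] + 1e-12)
    n_t = int(ncr_like_cohort["treated"].sum())
    assert len(data) <= 2 * n_t


def test_matching_improves_balance(ncr_like_cohort):
    model = fit_propensity(ncr_like_cohort, selection="none")
    sample = match_pairs(ncr_like_cohort, model, caliper_rule="0.2sd")
    before = standardized_mean_differences(ncr_like_cohort)
    after = standardized_mean_differences(sample.data)
    assert max(abs(v) for v in after.values()) < 0.25
    assert np.mean([abs(v) for v in after.values()]) < np.mean(
        [abs(v) for v in before.values()]
    )


def test_matching_empty_when_caliper_unsatisfiable():
    treated = np.array([1, 0])
    co = _toy_cohort(treated)
    model = _dummy_model([0.9, 0.1])
    with pytest.warns(UserWarning, match="no pairs"):
        sample = match_pairs(co, model, caliper_rule=0.01)
    assert sample.data.empty


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------


def test_ipw_constant_score_gives_unit_weights():
    treated = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    co = _toy_cohort(treated)
    model = _dummy_model(np.full(10, treated.mean()))
    sample = ipw_weights(co, model, truncate=None)
    assert np.allclose(sample.data["ipw_weight"], 1.0)


def test_ipw_weight_sum_near_n(ncr_like_cohort):
    model = fit_propensity(ncr_like_cohort, selection="none")
    sample = ipw_weights(ncr_like_cohort, model)
    n = len(ncr_like_cohort)
    assert abs(sample.data["ipw_weight"].sum() - n) / n < 0.05
    assert (sample.data["ipw_weight"] > 0).all()


def test_ipw_balances_covariates_large_n():
    co = simulate_registry(registry_preset(seed=4, n=50000))
    model = fit_propensity(co, selection="none")
    sample = ipw_weights(co, model)
    smd = standardized_mean_differences(co, weights=sample.data["ipw_weight"].to_numpy())
    assert max(abs(v) for v in smd.values()) < 0.1


def test_ipw_rejects_boundary_scores():
    co = _toy_cohort(np.array([1, 0, 0, 0]))
    model = _dummy_model([0.5, 0.5, 0.5, 0.5])
    model.scores = np.array([1.0, 0.5, 0.5, 0.5])
    with pytest.raises(ValueError, match="strictly inside"):
        ipw_weights(co, model)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def test_stratify_quintiles_partition():
    co = _toy_cohort(np.r_[np.ones(100, int), np.zeros(900, int)])
    model = _dummy_model(np.linspace(0.01, 0.99, 1000))
    sample = stratify(co, model, k=5)
    sizes = sample.data.groupby("stratum").size()
    assert list(sizes) == [200] * 5
    assert sample.data["stratum"].notna().all()


def test_stratify_constant_scores_error():
    co = _toy_cohort(np.array([1, 0, 0, 0, 0, 0]))
    model = _dummy_model(np.full(6, 0.2))
    with pytest.raises(ValueError, match="distinct"):
        stratify(co, model, k=5)


def test_stratify_within_range_smaller_than_between(ncr_like_cohort):
    model = fit_propensity(ncr_like_cohort, selection="none")
    sample = stratify(ncr_like_cohort, model, k=5)
    s = pd.Series(model.scores)
    g = sample.data["stratum"]
    within = s.groupby(g.to_numpy()).apply(lambda v: v.max() - v.min()).max()
    between = s.max() - s.min()
    assert within < between


# ---------------------------------------------------------------------------
# effect estimation
# ---------------------------------------------------------------------------


def test_effects_agree_without_confounding():
    zero = {k: 0.0 for k in registry_preset().assignment_coefficients}
    co = simulate_registry(
        registry_preset(seed=5, n=20000, assignment_coefficients=zero)
    )
    model = fit_propensity(co, selection="none")
    naive = estimate_effect(co, variant="naive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matched = estimate_effect(match_pairs(co, model, "0.2sd"))
        weighted = estimate_effect(ipw_weights(co, model))
        strat = estimate_effect(stratify(co, model))
    for fit in (matched, weighted, strat):
        assert abs(fit.log_hr - naive.log_hr) < 0.15
        lo, hi = fit.ci
        assert lo < 1.0 < hi  # truth is HR 1


def test_stratified_pool_within_stratum_range(ncr_like_cohort):
    model = fit_propensity(ncr_like_cohort, selection="none")
    sample = stratify(ncr_like_cohort, model, k=5)
    from kmpool import cox_fit
    from kmpool.propensity import OUTCOME_COVARIATES, _encode

    per = []
    for _, sub in sample.data.groupby("stratum"):
        if sub["treated"].nunique() < 2 or sub["event"].sum() == 0:
            continue
        X = _encode(sub, float(sub["age_years"].mean()))[list(OUTCOME_COVARIATES)]
        try:
            per.append(
                cox_fit(
                    sub["time_months"], sub["event"], sub["treated"].astype(float),
                    covariates=X,
                ).log_hr
            )
        except Exception:
            continue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = estimate_effect(sample)
    assert min(per) - 1e-9 <= pooled.log_hr <= max(per) + 1e-9


def test_estimate_effect_validation(ncr_like_cohort):
    with pytest.raises(ValueError, match="empty"):
        estimate_effect(ncr_like_cohort.iloc[0:0], variant="naive")
    with pytest.raises(ValueError, match="unknown variant"):
        estimate_effect(ncr_like_cohort, variant="bogus")
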