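"""Propensity-score adjustment of the observational (registry) cohort.

The treated fraction in the registry cohort is small and strongly
covariate-dependent (confounding by indication), so an unadjusted Cox
model is biased. Three corrections, all built on a logistic
propensity model e(x) = P(treated | x), are provided:

* 1:1 nearest-neighbour matching without replacement (exact-score caliper
  or 0.2 * SD of the logit propensity score),
* inverse-propensity weighting (stabilized ATE weights, scores truncated
  to [0.01, 0.99] by default),
* stratification into propensity-score quintiles with inverse-variance
  pooling of per-stratum log hazard ratios.

Effect estimation for each adjusted sample is a multivariate Cox model on
age, pT stage, evaluated lymph nodes, tumor site and differentiation
grade, with pair-clustered (matched) or sandwich (weighted) robust
standard errors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survival import CoxFit, CoxConvergenceError, cox_fit

__all__ = [
    "PropensityModel",
    "AdjustedSample",
    "fit_propensity",
    "match_pairs",
    "ipw_weights",
    "stratify",
    "estimate_effect",
    "standardized_mean_differences",
    "CANDIDATE_COVARIATES",
    "OUTCOME_COVARIATES",
]

CANDIDATE_COVARIATES = ("age", "male", "pt_t4", "nodes_lt10", "site_right", "diff_poor")
# covariates of the multivariate survival models (sex is not retained)
OUTCOME_COVARIATES = ("age", "pt_t4", "nodes_lt10", "site_right", "diff_poor")


def _encode(cohort: pd.DataFrame, age_center: float | None = None) -> pd.DataFrame:
    """Numeric design columns from the cohort's categorical schema."""
    if age_center is None:
        age_center = float(cohort["age_years"].mean())
    return pd.DataFrame(
        {
            "age": cohort["age_years"].to_numpy(dtype=float) - age_center,
            "male": (cohort["sex"] == "M").astype(float).to_numpy(),
            "pt_t4": (cohort["pt_stage"] == "T4").astype(float).to_numpy(),
            "nodes_lt10": cohort["nodes_lt10"].astype(float).to_numpy(),
            "site_right": (cohort["site"] == "right").astype(float).to_numpy(),
            "diff_poor": cohort["diff_poor"].astype(float).to_numpy(),
        },
        index=cohort.index,
    )


@dataclass
class PropensityModel:
    """Fitted logistic treatment-assignment model."""

    terms: list
    coefficients: dict
    scores: np.ndarray  # e(x) in (0, 1), aligned with the cohort rows
    logit_scores: np.ndarray
    sd_logit: float
    aic: float
    age_center: float


@dataclass
class AdjustedSample:
    """A propensity-adjusted view of the cohort.

    ``data`` carries the rows entering effect estimation plus, depending on
    the variant, a ``pair_id``, ``ipw_weight`` or ``stratum`` column.
    """

    variant: str  # matched | weighted | stratified
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _interaction_cols(X: pd.DataFrame, terms) -> pd.DataFrame:
    out = X[list(terms)].copy()
    for a, b in itertools.combinations(terms, 2):
        out[f"{a}:{b}"] = X[a] * X[b]
    return out


def _find_separator(y, X: pd.DataFrame):
    """Name a covariate whose levels fully determine treatment, if any."""
    for col in X.columns:
        vals = X[col]
        if vals.nunique() <= 10 and all(
            np.unique(y[vals == v]).size <= 1 for v in vals.unique()
        ):
            return col
    return None


def _logit_fit(y, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as exc:
        bad = _find_separator(y, X)
        raise ValueError(
            "perfect (or quasi-perfect) separation: covariate "
            f"{bad!r} determines treatment"
            if bad is not None
            else f"logistic fit failed (singular design): {exc}"
        ) from exc
    return res


def fit_propensity(
    cohort: pd.DataFrame,
    candidates=CANDIDATE_COVARIATES,
    selection: str = "aic_backward",
    include_interactions: bool = False,
) -> PropensityModel:
    """Logistic propensity model with optional backward AIC selection.

    The candidate set is the main effects (and, when requested, all
    pairwise covariate-by-covariate interactions); backward elimination
    drops the term whose removal improves AIC most, respecting the
    hierarchy that a main effect stays while one of its interactions is in
    the model.
    """
    y = cohort["treated"].to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("cohort must contain both treated and untreated patients")
    age_center = float(cohort["age_years"].mean())
    Xall = _encode(cohort, age_center)
    X = _interaction_cols(Xall, candidates) if include_interactions else Xall[list(candidates)]
    terms = list(X.columns)

    def check_separation(res, cols):
        big = np.abs(res.params.drop("const", errors="ignore")) > 20
        if big.any():
            bad = big[big].index[0]
            raise ValueError(
                f"perfect (or quasi-perfect) separation: covariate {bad!r} "
                "determines treatment"
            )

    res = _logit_fit(y, X[terms])
    check_separation(res, terms)
    if selection == "aic_backward":
        improved = True
        while improved and terms:
            improved = False
            best_aic, best_terms, best_res = res.aic, None, None
            for t in terms:
                if ":" not in t and any(
                    ":" in u and t in u.split(":") for u in terms
                ):
                    continue  # keep main effects under their interactions
                trial = [u for u in terms if u != t]
                cand = _logit_fit(y, X[trial]) if trial else _logit_fit(
                    y, pd.DataFrame(index=X.index)
                )
                if cand.aic < best_aic - 1e-9:
                    best_aic, best_terms, best_res = cand.aic, trial, cand
            if best_terms is not None:
                terms, res = best_terms, best_res
                improved = True
    elif selection != "none":
        raise ValueError(f"unknown selection rule {selection!r}")

    scores = np.asarray(res.predict(sm.add_constant(X[terms], has_constant="add")))
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    logit = np.log(scores / (1 - scores))
    return PropensityModel(
        terms=terms,
        coefficients=dict(res.params),
        scores=scores,
        logit_scores=logit,
        sd_logit=float(np.std(logit, ddof=1)),
        aic=float(res.aic),
        age_center=age_center,
    )


def match_pairs(cohort: pd.DataFrame, model: PropensityModel, caliper_rule="0.2sd") -> AdjustedSample:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated patients are processed in descending propensity-score order;
    each takes the closest unmatched control within the caliper.
    ``caliper_rule`` is ``"exact"`` (score distance <= 1e-10), ``"0.2sd"``
    (0.2 times the SD of the logit propensity score) or a numeric score
    distance. Unmatched treated patients are dropped and counted.
    """
    if caliper_rule == "exact":
        caliper = 1e-10
    elif caliper_rule == "0.2sd":
        caliper = 0.2 * model.sd_logit
    else:
        caliper = float(caliper_rule)

    ps = model.scores
    treated_idx = np.flatnonzero(cohort["treated"].to_numpy() == 1)
    control_idx = np.flatnonzero(cohort["treated"].to_numpy() == 0)
    order = treated_idx[np.argsort(-ps[treated_idx], kind="mergesort")]
    ctrl_ps = ps[control_idx]
    ctrl_order = np.argsort(ctrl_ps, kind="mergesort")
    ctrl_sorted = control_idx[ctrl_order]
    ctrl_ps_sorted = ctrl_ps[ctrl_order]
    used = np.zeros(ctrl_sorted.size, dtype=bool)

    pairs = []
    dropped = 0
    for ti in order:
        target = ps[ti]
        lo = np.searchsorted(ctrl_ps_sorted, target - caliper, side="left")
        hi = np.searchsorted(ctrl_ps_sorted, target + caliper, side="right")
        cand = np.flatnonzero(~used[lo:hi]) + lo
        if cand.size == 0:
            dropped += 1
            continue
        j = cand[np.argmin(np.abs(ctrl_ps_sorted[cand] - target))]
        if abs(ctrl_ps_sorted[j] - target) > caliper:
            dropped += 1
            continue
        used[j] = True
        pairs.append((ti, ctrl_sorted[j]))

    if not pairs:
        warnings.warn("no pairs satisfy the caliper; matched sample is empty", stacklevel=2)
        data = cohort.iloc[:0].copy()
        data["pair_id"] = pd.Series(dtype=int)
    else:
        rows, pair_ids = [], []
        for pid, (ti, ci) in enumerate(pairs):
            rows.extend([ti, ci])
            pair_ids.extend([pid, pid])
        data = cohort.iloc[rows].copy()
        data["pair_id"] = pair_ids
    return AdjustedSample(
        variant="matched",
        data=data.reset_index(drop=True),
        provenance={
            "caliper_rule": str(caliper_rule),
            "caliper": caliper,
            "n_pairs": len(pairs),
            "n_treated_unmatched": dropped,
        },
    )


def ipw_weights(
    cohort: pd.DataFrame,
    model: PropensityModel,
    estimand: str = "ATE",
    stabilized: bool = True,
    truncate: tuple | None = (0.01, 0.99),
) -> AdjustedSample:
    """Inverse-propensity weights for the average treatment effect.

    Stabilized weights are P(T=1)/e(x) for the treated and
    P(T=0)/(1-e(x)) for the untreated, so they average to about 1 and sum
    to about n. Scores may be truncated (default [0.01, 0.99]) to bound
    the weights.
    """
    if estimand != "ATE":
        raise ValueError("only the ATE estimand is implemented")
    e = model.scores
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("propensity scores must be strictly inside (0, 1)")
    if truncate is not None:
        e = np.clip(e, truncate[0], truncate[1])
    t = cohort["treated"].to_numpy(dtype=float)
    p1 = float(t.mean())
    if stabilized:
        w = np.where(t == 1, p1 / e, (1 - p1) / (1 - e))
    else:
        w = np.where(t == 1, 1.0 / e, 1.0 / (1 - e))
    data = cohort.copy()
    data["ipw_weight"] = w
    return AdjustedSample(
        variant="weighted",
        data=data,
        provenance={
            "estimand": estimand,
            "stabilized": stabilized,
            "truncate": list(truncate) if truncate else None,
            "weight_sum": float(w.sum()),
        },
    )


def stratify(cohort: pd.DataFrame, model: PropensityModel, k: int = 5) -> AdjustedSample:
    """Partition the cohort into k propensity-score quantile strata."""
    scores = model.scores
    if np.unique(scores).size < k:
        raise ValueError(f"need at least {k} distinct propensity scores to form {k} strata")
    strata = pd.qcut(scores, k, labels=False, duplicates="drop")
    if pd.Series(strata).nunique() < k:
        raise ValueError("propensity scores too coarse for the requested strata")
    data = cohort.copy()
    data["stratum"] = np.asarray(strata, dtype=int)
    counts = (
        data.groupby("stratum")["treated"].agg(["size", "sum"]).rename(
            columns={"size": "n", "sum": "n_treated"}
        )
    )
    return AdjustedSample(
        variant="stratified",
        data=data,
        provenance={"k": k, "strata_counts": counts.to_dict("index")},
    )


def _outcome_design(df: pd.DataFrame, covariates, age_center: float) -> pd.DataFrame:
    enc = _encode(df, age_center)
    return enc[list(covariates)]


def estimate_effect(
    sample,
    covariates=OUTCOME_COVARIATES,
    variant: str | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Treatment-effect Cox fit for a raw cohort or an adjusted sample.

    naive: unadjusted Cox on the full cohort. matched: multivariate Cox
    with pair-clustered robust SE. weighted: weighted multivariate Cox with
    sandwich SE. stratified: per-stratum multivariate Cox pooled by
    inverse-variance averaging of the log hazard ratios; strata with no
    treated patients, no events, or a degenerate fit are excluded with a
    warning.
    """
    if isinstance(sample, AdjustedSample):
        variant = variant or sample.variant
        df = sample.data
    else:
        variant = variant or "naive"
        df = sample
    if df.empty:
        raise ValueError("cannot estimate an effect on an empty sample")
    age_center = float(df["age_years"].mean())
    args = (
        df["time_months"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
        df["treated"].to_numpy(dtype=float),
    )
    if variant == "naive":
        return cox_fit(*args, ties=ties)
    if variant == "matched":
        X = _outcome_design(df, covariates, age_center)
        return cox_fit(*args, covariates=X, ties=ties, robust=True, cluster=df["pair_id"].to_numpy())
    if variant == "weighted":
        X = _outcome_design(df, covariates, age_center)
        return cox_fit(
            *args,
            covariates=X,
            weights=df["ipw_weight"].to_numpy(dtype=float),
            ties=ties,
            robust=True,
        )
    if variant == "stratified":
        betas, variances, n_tot, ev_tot = [], [], 0, 0
        for s, sub in df.groupby("stratum"):
            if sub["treated"].nunique() < 2 or sub["event"].sum() == 0:
                warnings.warn(f"stratum {s}: no treated patients or no events; excluded", stacklevel=2)
                continue
            try:
                X = _outcome_design(sub, covariates, age_center)
                f = cox_fit(
                    sub["time_months"].to_numpy(dtype=float),
                    sub["event"].to_numpy(dtype=int),
                    sub["treated"].to_numpy(dtype=float),
                    covariates=X,
                    ties=ties,
                )
            except (CoxConvergenceError, ValueError) as exc:
                warnings.warn(f"stratum {s}: fit failed ({exc}); excluded", stacklevel=2)
                continue
            betas.append(f.log_hr)
            variances.append(f.se**2)
            n_tot += f.n
            ev_tot += f.events
        if not betas:
            raise ValueError("no stratum produced a usable fit")
        wts = 1.0 / np.asarray(variances)
        beta = float(np.sum(wts * np.asarray(betas)) / wts.sum())
        se = float(np.sqrt(1.0 / wts.sum()))
        tsub = df["treated"].to_numpy()
        return CoxFit(
            log_hr=beta,
            se=se,
            n=n_tot,
            events=ev_tot,
            ties=ties,
            coefficients={"treatment": beta},
            n_per_arm={"control": int((tsub == 0).sum()), "treated": int((tsub == 1).sum())},
            events_per_arm={},
        )
    raise ValueError(f"unknown variant {variant!r}")


def standardized_mean_differences(
    df: pd.DataFrame, covariates=OUTCOME_COVARIATES, weights=None
) -> dict:
    """Treated-vs-control standardized mean differences (balance check)."""
    enc = _encode(df, float(df["age_years"].mean()))
    t = df["treated"].to_numpy(dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for c in covariates:
        x = enc[c].to_numpy()
        m1 = np.average(x[t == 1], weights=w[t == 1])
        m0 = np.average(x[t == 0], weights=w[t == 0])
        v1 = np.average((x[t == 1] - m1) ** 2, weights=w[t == 1])
        v0 = np.average((x[t == 0] - m0) ** 2, weights=w[t == 0])
        denom = np.sqrt((v1 + v0) / 2)
        out[c] = float((m1 - m0) / denom) if denom > 0 else 0.0
    return out
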