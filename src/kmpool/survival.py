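"""Kaplan-Meier estimation and Cox proportional-hazards fitting.

Implements the pooled-trial ("RCT track") survival machinery: the
product-limit estimator with Greenwood variance, a Newton-Raphson Cox
partial-likelihood engine (Efron or Breslow tie handling, case weights,
offsets, cluster-robust sandwich variance), a multilevel Cox model with a
log-normal per-trial random intercept estimated by penalized partial
likelihood with a Laplace-approximated profile likelihood for the
random-effect variance, and a parametric Weibull proportional-hazards fit.

The single engine is shared by the plain, multilevel, weighted and
matched-sample analyses so that tie handling and convergence behaviour are
identical across the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "FrailtyCoxFit",
    "WeibullPHFit",
    "PooledComparisonSpec",
    "CoxConvergenceError",
    "km_estimate",
    "cox_fit",
    "multilevel_cox_fit",
    "pooled_comparison",
    "weibull_ph_fit",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class CoxConvergenceError(RuntimeError):
    """Raised when the partial likelihood has no finite maximizer
    (monotone likelihood / separation) or Newton-Raphson fails."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group.

    ``times`` starts at 0 with survival 1.0 and zero variance; ``variance``
    is the Greenwood estimate of Var[S(t)]; ``at_risk`` is the number under
    observation just before each time.
    """

    label: str
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray
    n: int
    events: int

    def survival_at(self, t: float) -> float:
        """S(t) by step-function (last value carried forward) semantics."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.variance[max(idx, 0)])


@dataclass
class CoxFit:
    """Hazard-ratio estimate from a Cox model.

    ``log_hr``/``se`` refer to the treatment coefficient; the CI is Wald on
    the log scale and the p-value is a two-sided normal (Wald) test.
    """

    log_hr: float
    se: float
    n: int
    events: int
    ties: str = "efron"
    label: str = "treatment"
    coefficients: dict = field(default_factory=dict)
    n_per_arm: dict = field(default_factory=dict)
    events_per_arm: dict = field(default_factory=dict)

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_hr - Z95 * self.se)),
            float(np.exp(self.log_hr + Z95 * self.se)),
        )

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 1.0 if self.log_hr == 0 else 0.0
        z = self.log_hr / self.se
        return float(2 * stats.norm.sf(abs(z)))

    def summary(self) -> dict:
        lo, hi = self.ci
        return {
            "hr": self.hr,
            "log_hr": self.log_hr,
            "se": self.se,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": self.p_value,
            "n": self.n,
            "events": self.events,
            "ties": self.ties,
            "n_per_arm": self.n_per_arm,
            "events_per_arm": self.events_per_arm,
        }


@dataclass
class FrailtyCoxFit(CoxFit):
    """Cox fit with a Normal(0, tau2) per-group intercept on the log hazard."""

    tau2: float = 0.0
    group_effects: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = super().summary()
        out["tau2"] = self.tau2
        out["group_effects"] = self.group_effects
        return out


@dataclass
class WeibullPHFit:
    """Maximum-likelihood Weibull proportional-hazards fit.

    Baseline cumulative hazard H0(t) = exp(alpha) * t**shape; shape == 1
    reduces to the exponential model. ``log_hr`` is the treatment effect on
    the log hazard (proportional-hazards scale)."""

    log_hr: float
    se: float
    shape: float
    log_scale: float
    n: int
    events: int
    loglik: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_hr - Z95 * self.se)),
            float(np.exp(self.log_hr + Z95 * self.se)),
        )


@dataclass
class PooledComparisonSpec:
    """Which two arms of each trial enter a pooled treatment comparison."""

    trial_arms: list  # of (trial_id, comparator_arm, treatment_arm)
    analysis: int = 1

    def validate(self) -> None:
        if not self.trial_arms:
            raise ValueError("pooled comparison spec lists no trials")
        for trial, ctrl, treat in self.trial_arms:
            if ctrl == treat:
                raise ValueError(
                    f"trial {trial!r}: comparator and treatment arm are both {ctrl!r}"
                )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(time, event, label: str = "") -> SurvivalCurve:
    """Product-limit survival curve with Greenwood variance.

    All-censored input is valid and yields a flat curve at 1.0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table  # index: times (starting at 0), observed, at_risk
    t = tab.index.to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    n_at_risk = tab["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_at_risk > 0, d / n_at_risk, 0.0)
        surv = np.cumprod(1.0 - frac)
        gw_terms = np.where(
            (n_at_risk > d) & (n_at_risk > 0), d / (n_at_risk * (n_at_risk - d)), 0.0
        )
        var = surv**2 * np.cumsum(gw_terms)
    if t[0] != 0.0:
        t = np.insert(t, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
        var = np.insert(var, 0, 0.0)
        n_at_risk = np.insert(n_at_risk, 0, time.size)
    return SurvivalCurve(
        label=label,
        times=t,
        survival=surv,
        variance=var,
        at_risk=n_at_risk.astype(int),
        n=int(time.size),
        events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood engine
# ---------------------------------------------------------------------------


def _sorted_inputs(time, event, X, weights, offset):
    order = np.argsort(time, kind="mergesort")
    return (
        time[order],
        event[order],
        X[order],
        weights[order],
        offset[order],
        order,
    )


def _partial_loglik(beta, time, event, X, weights, offset, ties):
    """Log partial likelihood with gradient and Hessian.

    Inputs must be sorted ascending by time. Breslow contributions are fully
    vectorized across event times; Efron corrections loop over tied groups
    only (registry data has essentially no ties, reconstructed data has few
    distinct event times).
    """
    n, p = X.shape
    eta = X @ beta + offset
    eta = np.clip(eta, -200, 200)
    r = weights * np.exp(eta)
    rx = r[:, None] * X
    rxx = rx[:, :, None] * X[:, None, :]

    # suffix sums: suf0[i] = sum_{j >= i} r_j, etc.
    suf0 = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    suf1 = np.concatenate([np.cumsum(rx[::-1], axis=0)[::-1], np.zeros((1, p))])
    suf2 = np.concatenate([np.cumsum(rxx[::-1], axis=0)[::-1], np.zeros((1, p, p))])

    ev = event.astype(bool)
    t_ev = time[ev]
    if t_ev.size == 0:
        raise ValueError("no events in sample")
    uniq, first, counts = np.unique(t_ev, return_index=True, return_counts=True)
    g = uniq.size

    w_ev = weights[ev]
    r_ev = r[ev]
    rx_ev = rx[ev]
    rxx_ev = rxx[ev]
    X_ev = X[ev]
    eta_ev = eta[ev]

    wD = np.add.reduceat(w_ev, first)  # weighted deaths per unique time
    wetaD = np.add.reduceat(w_ev * eta_ev, first)
    wXD = np.add.reduceat(w_ev[:, None] * X_ev, first, axis=0)
    s0D = np.add.reduceat(r_ev, first)
    s1D = np.add.reduceat(rx_ev, first, axis=0)
    s2D = np.add.reduceat(rxx_ev, first, axis=0)

    pos = np.searchsorted(time, uniq, side="left")
    R0 = suf0[pos]
    R1 = suf1[pos]
    R2 = suf2[pos]

    # Breslow-style bulk terms
    ll = float(wetaD.sum() - np.sum(wD * np.log(R0)))
    grad = wXD.sum(axis=0) - np.einsum("g,gp->p", wD / R0, R1)
    hess = -(
        np.einsum("g,gpq->pq", wD / R0, R2)
        - np.einsum("g,gp,gq->pq", wD / R0**2, R1, R1)
    )

    if ties == "efron":
        for k in np.nonzero(counts > 1)[0]:
            m = counts[k]
            fr = np.arange(m) / m
            R0l = R0[k] - fr * s0D[k]
            R1l = R1[k][None, :] - fr[:, None] * s1D[k]
            R2l = R2[k][None, :, :] - fr[:, None, None] * s2D[k]
            wbar = wD[k] / m
            # replace the Breslow term for this group with the Efron term
            ll += wD[k] * np.log(R0[k]) - wbar * np.log(R0l).sum()
            grad += wD[k] * R1[k] / R0[k] - wbar * (R1l / R0l[:, None]).sum(axis=0)
            hess += wD[k] / R0[k] * R2[k] - wD[k] / R0[k] ** 2 * np.outer(R1[k], R1[k])
            hess -= wbar * (
                np.einsum("l,lpq->pq", 1.0 / R0l, R2l)
                - np.einsum("l,lp,lq->pq", 1.0 / R0l**2, R1l, R1l)
            )
    elif ties != "breslow":
        raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, hess


def _newton_cox(
    time,
    event,
    X,
    weights=None,
    offset=None,
    ties="efron",
    penalty=None,
    beta0=None,
    tol=1e-9,
    max_iter=100,
):
    """Maximize the (optionally ridge-penalized) partial likelihood.

    ``penalty`` is a length-p vector P adding -0.5 * sum(P_k beta_k^2); it
    carries the random-effect shrinkage in the multilevel model. Returns
    (beta, loglik, grad, hess) where grad/hess are of the *penalized*
    objective at the solution and loglik is the unpenalized partial
    log-likelihood.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    n, p = X.shape
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    penalty = np.zeros(p) if penalty is None else np.asarray(penalty, dtype=float)

    time, event, X, weights, offset, _ = _sorted_inputs(time, event, X, weights, offset)

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def objective(b):
        ll, g, h = _partial_loglik(b, time, event, X, weights, offset, ties)
        return ll - 0.5 * np.sum(penalty * b * b), g - penalty * b, h - np.diag(penalty)

    obj, grad, hess = objective(beta)
    best_gmax = np.inf
    stalled = 0
    for _ in range(max_iter):
        gmax = np.max(np.abs(grad))
        if gmax < tol:
            break
        # below 1e-6 the score is already within the float64 noise floor of
        # large objectives; stop once it stagnates instead of dithering
        if gmax < 1e-6:
            stalled = stalled + 1 if gmax >= 0.5 * best_gmax else 0
            if stalled >= 2:
                break
        best_gmax = min(best_gmax, gmax)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        scale = 1.0
        slack = 1e-11 * max(1.0, abs(obj))
        for _half in range(30):
            cand = beta + scale * step
            cobj, cgrad, chess = objective(cand)
            if np.isfinite(cobj) and cobj >= obj - slack:
                break
            scale *= 0.5
        else:
            if gmax < 1e-6:  # cannot improve further in floating point
                break
            raise CoxConvergenceError("step-halving failed to increase likelihood")
        beta, obj, grad, hess = cand, cobj, cgrad, chess
        if np.max(np.abs(beta)) > 15:
            raise CoxConvergenceError(
                "coefficient diverging (|beta| > 15): monotone partial likelihood, "
                "the risk sets are completely separated by a covariate"
            )
    else:
        if np.max(np.abs(grad)) > 1e-4:
            raise CoxConvergenceError(
                f"Newton-Raphson did not converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(grad)):.3g})"
            )
    ll = obj + 0.5 * np.sum(penalty * beta * beta)
    return beta, ll, grad, hess


def _score_residuals(beta, time, event, X, weights, offset):
    """Per-subject weighted score residuals (Lin-Wei, Breslow form).

    Used for the robust sandwich variance; inputs need not be sorted.
    Returns an (n, p) array aligned with the input order.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    n, p = X.shape
    t_s, e_s, X_s, w_s, o_s, order = _sorted_inputs(time, event, X, weights, offset)
    r = w_s * np.exp(np.clip(X_s @ beta + o_s, -200, 200))
    rx = r[:, None] * X_s
    suf0 = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    suf1 = np.concatenate([np.cumsum(rx[::-1], axis=0)[::-1], np.zeros((1, p))])
    ev = e_s.astype(bool)
    t_ev = t_s[ev]
    uniq, first = np.unique(t_ev, return_index=True)
    wD = np.add.reduceat(w_s[ev], first)
    pos = np.searchsorted(t_s, uniq, side="left")
    R0 = suf0[pos]
    M = suf1[pos] / R0[:, None]  # risk-set weighted mean covariate at each event time
    # cumulative hazard-increment sums up to each subject's follow-up time
    G0_steps = np.cumsum(wD / R0)
    G1_steps = np.cumsum(wD[:, None] * M / R0[:, None], axis=0)
    idx = np.searchsorted(uniq, t_s, side="right") - 1
    G0 = np.where(idx >= 0, G0_steps[np.clip(idx, 0, None)], 0.0)
    G1 = np.where(idx[:, None] >= 0, G1_steps[np.clip(idx, 0, None)], 0.0)
    # event-time mean for each subject that has an event
    ev_idx = np.searchsorted(uniq, t_s)
    M_at = M[np.clip(ev_idx, 0, uniq.size - 1)]
    U = e_s[:, None] * (X_s - M_at) - (r / w_s)[:, None] * (X_s * G0[:, None] - G1)
    out = np.empty_like(U)
    out[order] = w_s[:, None] * U
    return out


def _arm_counts(treat, event):
    treat = np.asarray(treat).astype(int)
    event = np.asarray(event).astype(int)
    return (
        {"control": int((treat == 0).sum()), "treated": int((treat == 1).sum())},
        {"control": int(event[treat == 0].sum()), "treated": int(event[treat == 1].sum())},
    )


def cox_fit(
    time,
    event,
    treatment,
    covariates=None,
    weights=None,
    ties: str = "efron",
    robust: bool = False,
    cluster=None,
) -> CoxFit:
    """Cox proportional-hazards fit with treatment as the first covariate.

    Parameters
    ----------
    covariates : optional (n, k) array or DataFrame of adjustment covariates.
    weights : optional case weights (e.g. inverse-propensity weights).
    robust : report the sandwich (Lin-Wei) standard error; with ``cluster``
        given, residuals are summed within clusters first (matched pairs).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    treat = np.asarray(treatment, dtype=float)
    if event.sum() < 1:
        raise ValueError("Cox model requires at least one event")
    if np.all(treat == treat[0]):
        raise ValueError("treatment indicator does not vary")
    cols = ["treatment"]
    if covariates is None:
        X = treat[:, None]
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if hasattr(covariates, "columns"):
            cols += list(covariates.columns)
        else:
            cols += [f"x{i}" for i in range(C.shape[1])]
        X = np.column_stack([treat, C])
    w = None if weights is None else np.asarray(weights, dtype=float)

    beta, ll, grad, hess = _newton_cox(time, event, X, weights=w, ties=ties)
    info = -hess
    cov = np.linalg.inv(info)
    if robust:
        offs = np.zeros(time.size)
        U = _score_residuals(beta, time, event, X, np.ones_like(time) if w is None else w, offs)
        if cluster is not None:
            dfU = pd.DataFrame(U)
            dfU["_c"] = np.asarray(cluster)
            U = dfU.groupby("_c").sum().to_numpy()
        B = U.T @ U
        cov = cov @ B @ cov
    se = float(np.sqrt(cov[0, 0]))
    n_arm, ev_arm = _arm_counts(treat, event)
    return CoxFit(
        log_hr=float(beta[0]),
        se=se,
        n=int(time.size),
        events=int(event.sum()),
        ties=ties,
        coefficients=dict(zip(cols, beta.tolist())),
        n_per_arm=n_arm,
        events_per_arm=ev_arm,
    )


# ---------------------------------------------------------------------------
# multilevel (log-normal frailty) Cox
# ---------------------------------------------------------------------------


def multilevel_cox_fit(
    time,
    event,
    treatment,
    group,
    ties: str = "efron",
    tau2: float | None = None,
    tau2_bounds: tuple[float, float] = (1e-4, 4.0),
) -> FrailtyCoxFit:
    """Cox model with a Normal(0, tau2) per-group intercept on the log hazard.

    The random effects enter as a ridge-penalized block of group indicators;
    for a candidate tau2 the penalized partial likelihood is maximized
    jointly over (beta, b), and tau2 itself maximizes the Laplace-approximated
    integrated log-likelihood

        lp(tau2) = pl(beta, b) - b'b/(2 tau2)
                   - 0.5 log det(Hbb + I/tau2) - (K/2) log tau2,

    profiled over the fixed and random effects (the approach of penalized
    frailty Cox software). se(beta) comes from the full penalized
    information, so it reflects the random-effect uncertainty and is never
    smaller than the plain-model standard error on heterogeneous data.

    With ``tau2=0`` (or a profile maximum at the lower boundary) the model
    reduces exactly to the plain Cox fit.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    treat = np.asarray(treatment, dtype=float)
    groups, gidx = np.unique(np.asarray(group), return_inverse=True)
    K = groups.size
    plain = cox_fit(time, event, treat, ties=ties)
    if K < 2:
        warnings.warn(
            "fewer than 2 groups: random-effect variance not identifiable, "
            "returning the plain Cox fit",
            stacklevel=2,
        )
        return FrailtyCoxFit(
            **{k: getattr(plain, k) for k in ("log_hr", "se", "n", "events", "ties")},
            coefficients=plain.coefficients,
            n_per_arm=plain.n_per_arm,
            events_per_arm=plain.events_per_arm,
            tau2=0.0,
            group_effects={},
        )
    if tau2 is not None and tau2 == 0.0:
        return FrailtyCoxFit(
            **{k: getattr(plain, k) for k in ("log_hr", "se", "n", "events", "ties")},
            coefficients=plain.coefficients,
            n_per_arm=plain.n_per_arm,
            events_per_arm=plain.events_per_arm,
            tau2=0.0,
            group_effects={str(g): 0.0 for g in groups},
        )

    Z = np.zeros((time.size, K))
    Z[np.arange(time.size), gidx] = 1.0
    X = np.column_stack([treat, Z])

    state = {"beta": None}

    def inner_fit(theta):
        penalty = np.concatenate([[0.0], np.full(K, 1.0 / theta)])
        beta, ll, grad, hess = _newton_cox(
            time, event, X, ties=ties, penalty=penalty, beta0=state["beta"]
        )
        state["beta"] = beta
        return beta, ll, hess

    def profile_loglik(theta):
        beta, ll, hess = inner_fit(theta)
        b = beta[1:]
        Hbb_pen = -hess[1:, 1:]  # penalized information of the random block
        sign, logdet = np.linalg.slogdet(Hbb_pen)
        if sign <= 0:
            return -np.inf
        return ll - b @ b / (2 * theta) - 0.5 * logdet - 0.5 * K * np.log(theta)

    if tau2 is None:
        lo, hi = tau2_bounds
        res = optimize.minimize_scalar(
            lambda lt: -profile_loglik(np.exp(lt)),
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        tau2_hat = float(np.exp(res.x))
        if tau2_hat <= lo * 1.5:  # boundary: no evidence of heterogeneity
            fit0 = multilevel_cox_fit(time, event, treat, group, ties=ties, tau2=0.0)
            return fit0
    else:
        tau2_hat = float(tau2)

    beta, ll, hess = inner_fit(tau2_hat)
    info = -hess
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[0, 0]))
    n_arm, ev_arm = _arm_counts(treat, event)
    return FrailtyCoxFit(
        log_hr=float(beta[0]),
        se=se,
        n=int(time.size),
        events=int(event.sum()),
        ties=ties,
        coefficients={"treatment": float(beta[0])},
        n_per_arm=n_arm,
        events_per_arm=ev_arm,
        tau2=tau2_hat,
        group_effects={str(g): float(b) for g, b in zip(groups, beta[1:])},
    )


# ---------------------------------------------------------------------------
# pooled trial comparison
# ---------------------------------------------------------------------------


def pooled_comparison(
    ipd: pd.DataFrame, spec: PooledComparisonSpec, multilevel: bool = False, ties="efron"
):
    """Pool the two named arms of each trial and fit the treatment effect.

    ``ipd`` columns: trial_id, arm, time_months, event. Trial labels are
    preserved so the multilevel model can place a random intercept per trial.
    """
    spec.validate()
    frames = []
    for trial, ctrl, treat in spec.trial_arms:
        sub = ipd[ipd["trial_id"] == trial]
        for arm, flag in ((ctrl, 0), (treat, 1)):
            rows = sub[sub["arm"] == arm]
            if rows.empty:
                raise ValueError(f"trial {trial!r} has no records for arm {arm!r}")
            frames.append(rows.assign(_treat=flag))
    pooled = pd.concat(frames, ignore_index=True)
    args = (
        pooled["time_months"].to_numpy(),
        pooled["event"].to_numpy(),
        pooled["_treat"].to_numpy(),
    )
    if multilevel:
        fit = multilevel_cox_fit(*args, group=pooled["trial_id"].to_numpy(), ties=ties)
    else:
        fit = cox_fit(*args, ties=ties)
    return fit


# ---------------------------------------------------------------------------
# Weibull proportional hazards
# ---------------------------------------------------------------------------


def weibull_ph_fit(time, event, treatment) -> WeibullPHFit:
    """Weibull PH maximum-likelihood fit with a treatment effect.

    Parameterisation: H(t | x) = exp(alpha) * t**rho * exp(beta * x), so the
    treatment log hazard ratio is beta directly; rho = 1 is the exponential
    model. Standard errors come from the observed information (central
    finite differences of the analytic gradient).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    x = np.asarray(treatment, dtype=float)
    if event.sum() < 1:
        raise ValueError("Weibull fit requires at least one event")
    logt = np.log(np.maximum(time, 1e-12))
    d = event

    def negll_grad(params):
        alpha, u, beta = params
        rho = np.exp(u)
        Hi = np.exp(np.clip(alpha + beta * x + rho * logt, -500, 500))
        ll = np.sum(d * (alpha + u + (rho - 1.0) * logt + beta * x)) - Hi.sum()
        g_alpha = d.sum() - Hi.sum()
        g_u = np.sum(d * (1.0 + rho * logt)) - rho * np.sum(Hi * logt)
        g_beta = np.sum(d * x) - np.sum(Hi * x)
        return -ll, -np.array([g_alpha, g_u, g_beta])

    res = optimize.minimize(
        negll_grad, x0=np.zeros(3), jac=True, method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-4:
        raise CoxConvergenceError(f"Weibull fit did not converge: {res.message}")
    params = res.x
    # observed information by central differences of the gradient
    h = 1e-5
    H = np.zeros((3, 3))
    for j in range(3):
        ep = np.zeros(3)
        ep[j] = h
        gp = negll_grad(params + ep)[1]
        gm = negll_grad(params - ep)[1]
        H[:, j] = (gp - gm) / (2 * h)
    H = (H + H.T) / 2
    cov = np.linalg.inv(H)
    alpha, u, beta = params
    return WeibullPHFit(
        log_hr=float(beta),
        se=float(np.sqrt(cov[2, 2])),
        shape=float(np.exp(u)),
        log_scale=float(alpha),
        n=int(time.size),
        events=int(event.sum()),
        loglik=float(-res.fun),
    )
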