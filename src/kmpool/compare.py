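"""Interaction tests between independent hazard-ratio estimates.

The two analysis tracks (pooled-trial and registry-based) each yield a log
hazard ratio with a standard error. Because the underlying samples are
independent, the difference of the log HRs is approximately normal with
variance se1^2 + se2^2, giving the classical test for interaction between
two estimates. The significance threshold for the track comparison is
alpha = 0.10 (chosen to limit type II error); elsewhere 0.05 applies.

The same z-machinery checks homogeneity of 5-year DFS across pooled trial
arms, on the complementary log-log scale (variance-stabilizing and
range-respecting for survival probabilities) with delta-method variances
from the Greenwood estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["InteractionResult", "HomogeneityResult", "interaction_test", "homogeneity_test"]


@dataclass
class InteractionResult:
    """z-test on the difference of two independent log hazard ratios."""

    diff_log_hr: float
    se_diff: float
    z: float
    p_value: float
    ratio_of_hr: float
    ratio_ci: tuple
    alpha: float
    significant: bool
    labels: tuple = ("fit1", "fit2")

    def summary(self) -> dict:
        return {
            "diff_log_hr": self.diff_log_hr,
            "se_diff": self.se_diff,
            "z": self.z,
            "p_value": self.p_value,
            "ratio_of_hr": self.ratio_of_hr,
            "ratio_ci": list(self.ratio_ci),
            "alpha": self.alpha,
            "significant": self.significant,
            "labels": list(self.labels),
        }


@dataclass
class HomogeneityResult:
    """All pairwise 5-year-DFS comparisons across a set of curves."""

    pairwise: list  # of InteractionResult
    max_abs_z: float
    n_comparisons: int
    t: float


def _extract(fit):
    if hasattr(fit, "log_hr"):
        return float(fit.log_hr), float(fit.se)
    return float(fit["log_hr"]), float(fit["se"])


def interaction_test(fit1, fit2, alpha: float = 0.10, labels=("fit1", "fit2")) -> InteractionResult:
    """Compare two independent hazard-ratio estimates.

    z = (beta1 - beta2) / sqrt(se1^2 + se2^2), two-sided normal p-value,
    plus the ratio of hazard ratios exp(beta1 - beta2) with its 95% CI.
    """
    b1, s1 = _extract(fit1)
    b2, s2 = _extract(fit2)
    if not (np.isfinite(s1) and np.isfinite(s2)) or s1 < 0 or s2 < 0:
        raise ValueError("standard errors must be finite and non-negative")
    se = float(np.sqrt(s1**2 + s2**2))
    diff = b1 - b2
    if se == 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / se
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    z95 = stats.norm.ppf(0.975)
    return InteractionResult(
        diff_log_hr=float(diff),
        se_diff=se,
        z=float(z),
        p_value=p,
        ratio_of_hr=float(np.exp(diff)),
        ratio_ci=(float(np.exp(diff - z95 * se)), float(np.exp(diff + z95 * se))),
        alpha=alpha,
        significant=bool(p < alpha),
        labels=tuple(labels),
    )


def homogeneity_test(curves, t: float = 60.0, alpha: float = 0.05) -> HomogeneityResult:
    """Pairwise z-tests of S(t) across survival curves.

    Each curve's S(t) is transformed to log(-log S(t)); the delta-method
    variance is Var[S] / (S log S)^2 with Var[S] from Greenwood. Pairs with
    S(t) of exactly 0 or 1 are skipped with a warning (the transform is
    undefined there). p-values are reported unadjusted; ``n_comparisons``
    flags how many were made.
    """
    stats_at_t = []
    for c in curves:
        s = c.survival_at(t)
        v = c.variance_at(t)
        if s <= 0.0 or s >= 1.0:
            warnings.warn(
                f"curve {c.label!r}: S({t}) = {s}; complementary log-log undefined, skipped",
                stacklevel=2,
            )
            stats_at_t.append(None)
            continue
        g = np.log(-np.log(s))
        var_g = v / (s * np.log(s)) ** 2
        stats_at_t.append((c.label, g, var_g))
    results = []
    for a, b in combinations([x for x in stats_at_t if x is not None], 2):
        la, ga, va = a
        lb, gb, vb = b
        res = interaction_test(
            {"log_hr": ga, "se": float(np.sqrt(va))},
            {"log_hr": gb, "se": float(np.sqrt(vb))},
            alpha=alpha,
            labels=(la, lb),
        )
        results.append(res)
    max_z = max((abs(r.z) for r in results), default=0.0)
    return HomogeneityResult(
        pairwise=results, max_abs_z=float(max_z), n_comparisons=len(results), t=t
    )
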