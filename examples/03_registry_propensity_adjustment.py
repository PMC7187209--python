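"""Treatment effect in an observational registry cohort, before and after
propensity-score adjustment.

The simulated cohort mirrors a population-based registry of Stage II colon
cancer: only 5.9% receive adjuvant chemotherapy, and they are younger but
higher-risk (pT4, few evaluated nodes, poor differentiation). The true
treatment effect is null (HR 1), so any departure of the naive estimate
from 1 is confounding by indication.
"""

import warnings

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

cohort = simulate_registry(registry_preset(seed=11))
print(f"cohort: n={len(cohort)}, treated={cohort['treated'].sum()} "
      f"({100 * cohort['treated'].mean():.1f}%), events={cohort['event'].sum()}")

model = fit_propensity(cohort, include_interactions=True)
print(f"propensity model terms after backward AIC: {model.terms}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    matched0 = match_pairs(cohort, model, caliper_rule="exact")
    matched02 = match_pairs(cohort, model, caliper_rule="0.2sd")
    print(f"matched pairs: {matched0.provenance['n_pairs']} (caliper 0), "
          f"{matched02.provenance['n_pairs']} (caliper 0.2 SD logit PS)")

    fits = {
        "naive": estimate_effect(cohort, variant="naive"),
        "matched (0.2 SD)": estimate_effect(matched02),
        "weighted": estimate_effect(ipw_weights(cohort, model)),
        "stratified": estimate_effect(stratify(cohort, model, k=5)),
    }

for name, fit in fits.items():
    lo, hi = fit.ci
    print(f"{name:18s} HR {fit.hr:.2f} (95% CI {lo:.2f}; {hi:.2f})")

smd = standardized_mean_differences(matched02.data)
print("post-matching standardized mean differences:",
      {k: round(v, 2) for k, v in smd.items()})

# On average the naive HR drifts above 1 (treated patients carry worse
# tumours); the adjusted estimates centre on the true HR of 1 with wider
# intervals, and post-matching SMDs near 0 show the covariates balance.
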