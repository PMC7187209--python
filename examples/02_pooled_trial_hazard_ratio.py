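"""Pooled treatment effect across reconstructed trials, with and without a
per-trial random effect.

Seven monotherapy-vs-control trials are simulated at the study-like sizes
(true HR 0.77, between-trial SD 0.2 on the log hazard), collapsed to
published-style aggregates, reconstructed, pooled, and analysed with a
plain Cox model and a multilevel Cox model (Normal per-trial intercept on
the log hazard).
"""

from kmpool import PooledComparisonSpec, pooled_comparison, simulate_trial_ipd, trial_preset
from kmpool.pipeline import reconstruct_pooled

ipd = simulate_trial_ipd(trial_preset("monotherapy-vs-control", seed=11))
reconstructed, reports, notes = reconstruct_pooled(
    ipd, risk_interval=12.0, noise_sd=0.005, seed=11
)

spec = PooledComparisonSpec(
    trial_arms=[(t, "control", "mono") for t in sorted(reconstructed["trial_id"].unique())]
)
plain = pooled_comparison(reconstructed, spec, multilevel=False)
multi = pooled_comparison(reconstructed, spec, multilevel=True)

for name, fit in (("plain Cox", plain), ("multilevel Cox", multi)):
    lo, hi = fit.ci
    print(f"{name}: HR {fit.hr:.3f} (95% CI {lo:.3f}; {hi:.3f}), p = {fit.p_value:.3f}")
print(f"random-effect variance tau2 = {multi.tau2:.4f}")
print(f"patients {plain.n}, events {plain.events}")

# HR < 1 favours adjuvant treatment; the multilevel interval is at least as
# wide as the plain one because the per-trial intercept absorbs
# between-trial heterogeneity into the standard error.
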