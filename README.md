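# kmpool

Two-track estimation of an adjuvant-chemotherapy effect on disease-free
survival (DFS) in Stage II colon cancer, built as a reusable Python
library.

Clinical trials publish Kaplan-Meier curves and numbers-at-risk tables,
not patient records; population registries hold patient records, but
treatment there is confounded by indication (the few patients treated are
younger yet carry worse tumours). `kmpool` implements both halves of the
resulting analysis and the bridge between them:

1. **RCT track** — reconstruct pseudo individual-patient data (IPD) from
   digitized KM curves plus risk tables (the Hoyle–Henley curve-fitting
   idea: per risk interval, split the known number leaving the risk set
   into events and censorings by exhaustive integer search against the
   reported survival ratio), pool the reconstructed trials, and estimate
   the hazard ratio with a Cox model — plain, or multilevel with a
   Normal(0, τ²) per-trial intercept on the log hazard fitted by penalized
   partial likelihood with a Laplace-approximated profile for τ².
2. **RWD track** — estimate the same effect in a registry-style cohort
   with a naive Cox model and three propensity-score corrections:
   1:1 caliper matching, stabilized inverse-propensity weighting, and
   quintile stratification with inverse-variance pooling.
3. **Comparison** — an interaction z-test on the difference of the two
   log hazard ratios, z = (β₁ − β₂)/√(se₁² + se₂²), at α = 0.10.

A synthetic-data module generates both data sources with known ground
truth — multi-trial survival data with a trial-level random effect, and a
registry cohort with a 5.9% treated fraction and built-in confounding by
indication — so every stage is testable end to end without external data.
See `docs/methods.md` for the models, conventions and calibrations.

## Worked example

Simulate seven monotherapy-vs-control trials at study-like sizes
(true HR 0.77, between-trial SD 0.2), collapse each arm to a digitized
curve + yearly risk table, reconstruct, and pool:

```python
from kmpool import PooledComparisonSpec, pooled_comparison, simulate_trial_ipd, trial_preset
from kmpool.pipeline import reconstruct_pooled

ipd = simulate_trial_ipd(trial_preset("monotherapy-vs-control", seed=11))
rec, reports, notes = reconstruct_pooled(ipd, risk_interval=12.0, noise_sd=0.005, seed=11)
spec = PooledComparisonSpec([(t, "control", "mono") for t in sorted(rec["trial_id"].unique())])
print(pooled_comparison(rec, spec, multilevel=False).summary())
print(pooled_comparison(rec, spec, multilevel=True).summary())
```

Running `python examples/02_pooled_trial_hazard_ratio.py` (which does the
above) prints:

```
plain Cox: HR 0.794 (95% CI 0.706; 0.893), p = 0.000
multilevel Cox: HR 0.794 (95% CI 0.706; 0.893), p = 0.000
random-effect variance tau2 = 0.0008
patients 4479, events 1115
```

HR < 1 favours treatment: the pooled estimate recovers the preset's true
HR of 0.77 within sampling error, and with this seed's draw of trial
effects the estimated between-trial variance is close to the boundary, so
the multilevel interval barely widens. The registry example
(`examples/03_registry_propensity_adjustment.py`) shows confounding by
indication: the true treatment effect is null, yet the naive HR sits
above 1 because the treated carry worse tumours:

```
cohort: n=1947, treated=107 (5.5%), events=746
matched pairs: 59 (caliper 0), 107 (caliper 0.2 SD logit PS)
naive              HR 1.16 (95% CI 0.87; 1.56)
matched (0.2 SD)   HR 1.21 (95% CI 0.84; 1.74)
weighted           HR 0.80 (95% CI 0.51; 1.26)
stratified         HR 0.95 (95% CI 0.68; 1.32)
```

The other examples cover single-arm reconstruction with a fidelity report
(`01`) and the full two-track pipeline with interaction tests (`04`).
A thin CLI mirrors the stages:

```bash
km-pool simulate trial --seed 1 --out ipd.csv
km-pool reconstruct --curve curve.csv --risk risk.csv --arm control --trial t1 --out rec.csv
km-pool rct-pool --ipd rec.csv --multilevel --out fit.json
km-pool rwd-adjust --cohort cohort.csv --method ipw --out rwd.json
km-pool compare --fit-a fit.json --fit-b rwd.json --alpha 0.10
km-pool run --seed 1 --out results/
```

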