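# Methods

`kmpool` implements a two-track estimation of an adjuvant-treatment effect
on disease-free survival (DFS), with a synthetic-data module that supplies
ground truth for every stage. Times are months from surgery/randomization
throughout; 5-year DFS is S(60).

## Reconstruction of pseudo-IPD from published aggregates

Published trials report a Kaplan-Meier curve and a numbers-at-risk table,
not patient records. Between consecutive risk-table times T_j < T_{j+1},
the number leaving the risk set is known exactly, n_j − n_{j+1}; its split
into d_j events and c_j censorings is chosen by exhaustive integer search
so that the implied conditional survival matches the reported ratio
S(T_{j+1})/S(T_j). Censoring is modelled as uniform through the interval,
approximated by removing c_j/2 from the risk set before the events, so the
implied ratio is 1 − d_j/(n_j − c_j/2). Ties in the search break to the
smaller event count. Patients still at risk after the last risk-table time
form a terminal block: residual curve drops supply events and everyone
else is administratively censored at the curve's last time; because that
censoring happens at the very end, the half-interval correction is not
applied there.

Events are placed at the digitized step times, apportioned across the
steps of an interval proportionally to the drop sizes with
largest-remainder rounding (ties to the earlier step); this preserves the
visible curve shape. If digitization noise leaves an interval with events
but no visible step, the events fall at the interval midpoint. Non-terminal
censorings are spread evenly strictly inside their interval. Counts are
conserved by construction: the output has exactly n_1 records per arm.

Conventions worth knowing: survival at a time not on the digitized grid is
carried forward (step-function semantics); count intervals are half-open
[T_j, T_{j+1}) while curve drops at g with T_j < g ≤ T_{j+1} belong to
interval j, because the reported ratio S(T_{j+1})/S(T_j) includes a drop
exactly at T_{j+1} — for continuous data the boundary carries no mass.
Raw digitized coordinates are cleaned by clipping to [0,1], collapsing
duplicate times to the lowest value, prepending (0, 1), and a running
minimum (manual curve reading jitters in both directions).

**Exactness.** With zero digitization noise the round trip
aggregate → reconstruct reproduces the source KM exactly at every
risk-table time in two regimes: (i) no random censoring interior to the
risk intervals (administrative censoring at the end of follow-up only), in
which case the integer search provably recovers the true event counts and
the largest-remainder step allocation recovers the true per-step counts;
and (ii) an arbitrary censoring pattern when the risk table has an entry
between every pair of adjacent observed times. Interior random censoring
under a coarse risk table makes reconstruction approximate — that residual
error is what the fidelity report measures and what the hazard-ratio
recovery simulation bounds (mean |Δ log HR| < 0.05 against the direct-IPD
fit at 12-month risk tables, n = 2,000/arm).

## Survival models

The Cox partial likelihood is maximized by Newton–Raphson (tolerance 1e-9
on the score norm, at most 100 iterations, step-halving on likelihood
decrease, and a stagnation stop once the score is below 1e-6 and within
the float64 noise floor of the objective). Efron tie handling is the
default — reconstructed data are tie-heavy because events sit on digitized
step times — with Breslow available by flag. A diverging coefficient
(|β| > 15) raises a monotone-likelihood diagnostic rather than silently
returning a huge estimate. Confidence intervals are 95% Wald on the log-HR
scale. One engine serves all model variants (plain, weighted, penalized),
so tie handling and convergence behaviour are identical across the
pipeline; the test suite checks it against lifelines, against a
term-by-term brute-force Newton oracle, and against R `survival::coxph`.

The multilevel model adds a Normal(0, τ²) per-trial intercept on the log
hazard, entering as a ridge-penalized block of trial indicators. For fixed
τ² the penalized partial likelihood is maximized jointly over (β, b); τ²
maximizes the Laplace-approximated integrated likelihood

    lp(τ²) = pl(β̂, b̂) − b̂'b̂/(2τ²) − ½ log det(H_bb + I/τ²) − (K/2) log τ²,

profiled by bounded scalar search on log τ² over [1e-4, 4]. A maximum at
the lower boundary is reported as τ² = 0, which reduces exactly to the
plain fit. se(β) comes from the full penalized information, so it reflects
random-effect uncertainty; on heterogeneous trials it is never smaller
than the plain standard error (Schur complement), though with arms
balanced within trials the inflation is modest — a random intercept mostly
cancels out of a within-trial contrast. RCT-track models carry no
covariates: the reconstruction cannot supply any.

The parametric fit is a Weibull proportional-hazards model,
H(t|x) = exp(α)·t^ρ·exp(βx), by maximum likelihood (BFGS with analytic
gradient; observed information by central differences). ρ = 1 is the
exponential model, and β is directly the log hazard ratio.

## Registry track: propensity-score corrections

The propensity model is a logistic regression of treatment on gender, age,
pT stage, evaluated lymph nodes (<10 vs ≥10), differentiation grade and
tumor site, optionally with all pairwise covariate-by-covariate
interactions, pruned by backward AIC elimination (a main effect is kept
while any of its interactions remains). Three corrections use the fitted
scores e(x):

* **Matching** — greedy 1:1 nearest-neighbour without replacement, treated
  patients processed in descending score order. Calipers: "exact" (score
  distance ≤ 1e-10 — feasible because registry covariate patterns repeat;
  age is recorded in whole years) and 0.2·SD of the logit propensity
  score, applied as a distance on the score scale. Unmatched treated
  patients are dropped and counted.
* **Weighting** — stabilized ATE weights, P(T=t)/e(x) or P(T=t)/(1−e(x)),
  with scores truncated to [0.01, 0.99] by default to bound the weights;
  stabilized weights average ≈ 1.
* **Stratification** — quintiles of the score over the whole cohort;
  strata with no treated patients, no events, or a degenerate fit are
  excluded from pooling with a warning.

Effect estimation: naive = unadjusted Cox on the full cohort; matched and
weighted = multivariate Cox (age, pT stage, nodes, site, differentiation —
sex is not retained, matching the multivariate model convention of the
source analysis) with pair-clustered and sandwich robust standard errors
respectively; stratified = per-stratum multivariate Cox pooled by
fixed-effect inverse-variance averaging of the log HRs, which always lies
inside the range of the per-stratum estimates. Robust variances use
Lin–Wei score residuals in their Breslow form evaluated at the Efron
estimate; registry follow-up times are continuous, so the tie-form
difference is negligible.

## Track comparison

Two independent log hazard ratios are compared with
z = (β₁ − β₂)/√(se₁² + se₂²) and a two-sided normal p-value; the
RCT-vs-registry comparison uses α = 0.10 (limiting type II error), 0.05
elsewhere. Homogeneity of 5-year DFS across pooled arms uses the same
machinery on log(−log S(60)) with delta-method variances from the
Greenwood estimate — the complementary log-log scale is
variance-stabilizing and respects the (0,1) range. Pairwise p-values are
reported unadjusted with the number of comparisons flagged.

## Synthetic data: what it emulates, and what it does not

**Trials.** Event times are exponential by default (Weibull by shape
parameter), with the treatment effect and a Normal(0, sd²) per-trial
intercept on the log hazard — the generating counterpart of the multilevel
estimator. Censoring is exponential truncated by an administrative
cut-off. The monotherapy-vs-control preset uses seven trials at the
published stage-II arm sizes (224/225, 110/111, 84/84, 28/29, 60/61,
1480/1483, 248/252), true HR 0.77, control-arm rate −ln(0.77)/60 per month
(5-year DFS 0.77, the centre of the printed 0.74–0.80 range),
between-trial SD 0.2, censor rate 0.002/month, administrative cut-off 84
months. The combination-vs-monotherapy preset uses two trials (448/451,
359/360), true HR 0.93, monotherapy-arm 5-year DFS 0.80.

**Registry.** n = 1,947 with covariate marginals matching the published
cohort table: age ~ Normal(70.9, 11.0) rounded to whole years, pT4 10.0%,
<10 nodes 53.9%, right-sided 60.2%, poor differentiation 16.7%, male 52%.
Treatment follows a logistic model whose intercept is calibrated by
bisection to a 5.9% treated fraction; the covariate log-odds are set from
the published treated-vs-untreated contrasts (age −0.076/yr, pT4 +1.7,
<10 nodes +0.53, poor differentiation +0.8, site −0.06, male +0.1), so the
treated are about ten years younger but carry markedly worse tumours.
Outcome log-hazard effects are field-typical prognostic values (age
+0.015/yr, pT4 +0.8, <10 nodes +0.35, right +0.1, poor +0.5, male +0.1);
the default treatment effect is null. The covariance between the
assignment and outcome linear predictors is positive (≈ +0.09), so the
naive hazard ratio is biased upward — the same direction as the published
naive-vs-adjusted flip. The cohort's DFS event fraction is not published;
the baseline hazard 0.0045/month with censor rate 0.010/month and a
120-month administrative cut-off (≈27% events, median follow-up near 4.5
years) is this package's calibration choice.

Not emulated: overall survival, competing risks, time-varying treatment,
covariate-dependent censoring, measurement error in covariates, and any
unmeasured confounding — so passing tests show the estimators remove the
confounding they model, not that a real registry analysis is unbiased.
Trial covariates are not generated at all (the reconstruction provides
none). One global seed is split into named sub-streams per stage;
identical seeds give bit-identical outputs.

## Numerical and design choices

* Interval split search: exhaustive over all integer (d, c), ties to
  smaller d; infeasible risk tables are rejected at validation rather than
  silently renormalized.
* Treatment-assignment intercept: bisection on the expected treated
  fraction over the drawn covariates (the marginal rate, not the
  intercept, is the published quantity).
* Digitization noise: additive Gaussian on survival probability, repaired
  by running minimum and clipping.
* Profile search for τ²: bounded Brent on log τ², xatol 1e-3; warm starts
  across evaluations.
* "Caliper 0" is score equality within 1e-10; the 0.2·SD(logit) caliper
  follows the published description of the second matched sample.
* Stratified pooling is fixed-effect inverse variance; the pooled log HR
  is a convex combination of per-stratum log HRs.
* Degenerate inputs: all-censored KM input yields a flat curve (valid);
  Cox requires ≥1 event and a varying treatment indicator; stratification
  requires ≥ k distinct scores; interaction tests reject non-finite
  standard errors.

## Problem sizes used by the checks

The replicated acceptance checks run at the sizes the guarantees are
stated for: 100 replicates of seven 2,000-per-arm trials for multilevel
recovery, 100 replicates for reconstruction HR recovery, 200 replicates of
n = 5,000 cohorts for confounded-null coverage, 1,000 null replicates for
the interaction test's type-I error, and n = 50,000 for registry
marginals. The acceptance script runs each pipeline once at the preset
(study-like) sizes.

## Known limitations

* The multilevel model uses an intercept-only frailty; a random treatment
  effect per trial (which would widen the pooled CI substantially) is not
  implemented.
* The Laplace/profile τ² estimate is biased low with few trials (seven
  trials is few); the tests assert recovery of β, not of τ².
* Reconstruction fidelity degrades with coarse risk tables and heavy
  interior censoring; the fidelity report should be inspected whenever
  max deviation exceeds the digitization noise scale.
* The exact-caliper matched sample depends on duplicate covariate
  patterns; in cohorts with continuous covariates it can be empty (a
  warning, not an error).
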