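# Methods

## Model

Each trial contributes a 2×2 table: `events_treat / n_treat` in the
intervention arm and `events_ctrl / n_ctrl` in the control arm. The
Bayesian analysis is a logistic regression with the treatment indicator
as the only covariate,

    events_ctrl  ~ Binomial(n_ctrl,  inv_logit(α))
    events_treat ~ Binomial(n_treat, inv_logit(α + β))

so β is the log odds ratio of the intervention versus control; treat = 1
codes the intervention, making β > 0 a beneficial effect when the
outcome is oriented as a benefit. Priors are independent normals on the
log-odds scale: β ~ N(0, 2.5) and α ~ N(0, 10). These are the
conventional weakly informative defaults for logistic coefficients: a
slope SD of 2.5 keeps even huge odds ratios (|log OR| ≈ 5) inside two
prior SDs while regularizing separated or zero-event tables; the wide
intercept prior leaves the baseline rate essentially to the data. With
hundreds of patients per trial the posterior is dominated by the
likelihood and the posterior median of exp(β) tracks the sample odds
ratio closely. "Weakly informative" is a family, not a single prior;
the adequacy of this default for the shipped worked example is
quantified in the acceptance tests rather than assumed.

## Posterior summaries

* **Probability of direction (pd)** = max{Pr(β > 0), Pr(β < 0)},
  estimated as the corresponding fraction of posterior draws; draws
  exactly at zero belong to neither tail. Computing on the log-OR scale
  against 0 is identical to computing on the OR scale against 1 (the
  index is invariant to monotone sign-preserving transforms). Reported
  as a percentage with one decimal; the conversions
  `pd_to_p(pd) = 2(1 − pd)` and `p_to_pd(p) = 1 − p/2` implement the
  approximate correspondence with the two-sided P value.
* **ROPE_full** = fraction of draws with log(0.84) ≤ β ≤ log(1.20) for
  the default region of practical equivalence; the interval is closed,
  a measure-zero choice for continuous posteriors that makes discrete
  test fixtures deterministic. The (0.84, 1.20) band is a convention
  for negligible odds ratios and is overridable everywhere
  (`RopeInterval`); a context-specific equivalence margin is preferable
  when one exists.
* **Equal-tailed credible interval**: empirical ((1−level)/2,
  (1+level)/2) percentiles of the β draws (linear interpolation between
  order statistics), exponentiated.

## Frequentist block

The sample odds ratio is the cross-product estimator; degenerate tables
return sentinels (∞ when only the denominator vanishes, NaN when both
do) so cohort runs never abort. Fisher's exact P uses the two-sided
probability-mass rule (sum over tables with the observed margins whose
probability does not exceed the observed table's), the convention of R's
`fisher.test` and scipy. Two OR confidence intervals are available:
Wald, `exp(log OR ± z·√(1/a+1/b+1/c+1/d))`, requiring positive cells;
and exact-conditional, inverting the one-sided Fisher noncentral
hypergeometric tail tests at (1−level)/2 per side via Brent root-finding
on log ψ. The exact-conditional interval is the default companion to the
Fisher P (same conditional framework); on the shipped worked example it
is the method that reproduces the published interval, and a Wald request
on a zero-cell table falls back to it, recorded in `ci_method`.

## Sampler

The posterior is sampled by random-walk Metropolis on (α, β). The
proposal covariance comes from a Laplace approximation: damped Newton
iteration finds the posterior mode (the log posterior is strictly
concave, so it is unique and the iteration is safe even for zero-event
tables), and the inverse negative Hessian there, scaled by 2.38/√2 times
a scalar step size, shapes the proposal. During warmup (default 1,000
iterations per chain) the step size adapts by Robbins–Monro toward 35%
acceptance and is then frozen. Four chains run by default; the retained
total is 100,000 draws, which keeps the Monte-Carlo standard error of pd
and ROPE_full below ~0.1 percentage points and of the credible-interval
endpoints near 0.01 on the OR scale for trials of a few hundred
patients (effective sample sizes around 13,000).

Convergence is gated on split-R̂ of β (tolerance 1.01, two halves per
chain); failure emits a `ConvergenceWarning` and sets `converged=False`
on the result rather than raising, and the flag propagates into reports
and the CLI warnings section. Split-R̂ is computed in-package (the batch
path needs it vectorized) and is cross-checked against `arviz.rhat` in
the test suite; effective sample size comes from `arviz.ess`. Note that
short exploratory chains (a few hundred draws per chain) can exceed the
1.01 tolerance out of estimator noise alone; the default draw count does
not.

Two entry points share the sampling core: `fit_posterior` (one trial;
fully determined by the trial, prior and seed) and `fit_posterior_many`
(one vectorized pass over a batch of trials sharing a random stream —
reproducible for a fixed batch and seed, intended for simulation
studies). Cohort analysis uses per-trial `fit_posterior` with seeds
derived as `sha256(master_seed, trial_id)`, so cohort results are
order-independent and stable under subsetting.

## Synthetic cohorts

`generate_trial` simulates at the trial level: the control arm is
Binomial(n, p_ctrl) and the treatment arm Binomial(n, inv_logit(logit
p_ctrl + log OR_true)). `CohortSpec` defaults — 56 estimates, 50–500
patients per arm, control rates uniform on (0.2, 0.6), true log OR ~
N(0, 0.35) — mix null-ish and modest effects so cohorts span the full pd
and ROPE_full ranges, in the spirit of published multicenter
anesthesiology cohorts; they are illustrative, not estimates of any real
cohort's parameter distribution. Per-trial seeding is counter-based
(`SeedSequence(seed, i)`), so trial *i* is identical regardless of
cohort size.

What the generator does *not* emulate: patient-level covariates,
factorial or coprimary multiplicity (multiple estimates per study appear
only as independent rows), interim analyses, and outcome-orientation
heterogeneity across trials. Passing calibration tests on these cohorts
therefore demonstrates correctness of the inference machinery under the
assumed binomial model, not robustness to real-data violations of it.

## Simulation sizes in the test suite

Chosen as the package's own balance of statistical resolution and
runtime: credible-interval calibration over 500 prior-consistent
replicates at 100/arm (coverage checked within 95% ± 2%); Fisher type-I
error over 1,000 null replicates at 200/arm (0.05 ± 0.02 — Fisher is
conservative, so the observed rate sits slightly below nominal);
null-uniformity of 2(1 − pd) over 1,000 replicates at 200/arm
(Kolmogorov–Smirnov distance < 0.05); pd/ROPE monotonicity on the true
log-OR grid {0, 0.3, 0.6} with 40–60 trials per point at 300/arm; and a
56-estimate cohort at 20,000 draws per trial for the pd↔P
correspondence (Spearman ≤ −0.95, median |pd − (1 − P/2)| < 0.01).
Batch fits in these studies use 4,000 draws per trial, enough that
index-level Monte-Carlo noise (~1 percentage point) is small against the
tested effects.

## Numerical choices and edge cases

* Quantiles and IQRs use linear interpolation (numpy default); medians
  and IQRs of cohort summaries follow the same convention.
* pd on a posterior with an atom at exactly zero can fall below 0.5;
  this arises only with artificial discrete draw sets, and the behavior
  (zeros excluded from both tails) is documented and tested.
* Odds-ratio sentinels: ∞ and NaN are carried through reports as-is;
  Spearman correlations are rank-based and unaffected by monotone
  transformations of P.
* The dichotomization table bins pd at 97.5% and ROPE_full at 2.5%/97.5%
  (the customary decision cut points for these indices), and defines
  near-threshold discordant pairs by |P − α| < 0.02 with pd values
  within one percentage point of each other.
* Cohort-level medians of P, pd and ROPE_full for any *real* published
  cohort require that cohort's supplementary data; the pipeline ingests
  such data as the canonical CSV (`load_cohort`, optional `column_map`
  for renamed headers) and computes the same summaries it computes for
  synthetic cohorts.

## Known limitations

* Single binary covariate only: no covariate adjustment, no
  hierarchical pooling across trials, no elicited or external-evidence
  priors.
* The pd↔P correspondence is approximate; with strong priors, small
  samples, or small effects the Bayesian and frequentist summaries can
  legitimately diverge, and with weak priors plus small samples
  ROPE_full can overstate practical significance.
* Random-walk Metropolis is simple and auditable but has ~13% draw
  efficiency; draw counts trade directly against Monte-Carlo error.
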