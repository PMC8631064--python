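# Methods

`msmiss` studies a question that routinely collected health data force on
analysts: when time-varying confounders of a time-varying treatment are only
partially recorded, which missing-data strategy still yields unbiased
marginal structural model (MSM) estimates, and under which missingness
mechanism?  The package contains (i) a structural simulator with
treatment–confounder feedback, (ii) the standard two-stage MSM estimator
(stabilized inverse-probability-of-treatment weights + weighted least
squares), (iii) five missing-confounder strategies, and (iv) a replicate
driver that measures bias, Monte Carlo error, and coverage against a
g-formula truth oracle.

## Structural model

Per subject, with K = 3 treatment times (k = 0, 1, 2):

* `V ~ N(0, 1)` — an independent risk factor that affects only the outcome.
* `L1` — binary time-varying confounder. Baseline `L1_0 ~ Bernoulli(0.5)`;
  at k ≥ 1 the value is carried over exactly with probability π
  (`carryover`, default 0.5), otherwise redrawn from
  `logit P(L1_k=1) = -0.5 + 1.0·L1_{k-1}`.
* `L2` — continuous time-varying confounder. Baseline `N(0, 1)`; at k ≥ 1
  carried over with probability π, otherwise
  `L2_k = 0.3·L2_{k-1} + 0.5·A_{k-1} + N(0, 1)`.
* `A_k ~ Bernoulli(expit(α_k + 0.7·L1_k + 0.7·L2_k + 0.5·A_{k-1}))` with
  `A_{-1} = 0` and α = (−0.35, −0.6, −0.7).
* `Y = 1 + Σ_k 0.5·A_k + Σ_k 0.5·L1_k + Σ_k 0.5·L2_k + 0.5·V + N(0, 1)`.

Generation order is `V → L_0 → A_0 → L_1 → A_1 → L_2 → A_2 → Y`, so earlier
treatment feeds back into later confounders and later treatment responds to
current confounders — the setting in which ordinary regression adjustment
fails and weighting is required.

Two deliberate design choices:

* **Sticky carry-over.** The carry-over mixture makes exact repeats of the
  continuous confounder possible (probability π per transition), which the
  "constant" missingness mechanism needs: a value can only go unrecorded
  *because it did not change* if unchanged values actually occur.
* **Treatment effects travel only along linear paths.** Treatment enters the
  `L2` dynamics but not the `L1` dynamics.  Because every pathway from any
  `A_k` to `Y` is linear (direct, or through the linear `L2` chain), the
  counterfactual regime means are *exactly* additive in (a_0, a_1, a_2), so
  the additive MSM `E[Y^a] = β_int + Σ β_k a_k` is exactly correct rather
  than an approximation, and the estimand does not depend on how the 2^K
  regimes are weighted in the projection.  `L1` remains a genuine
  time-varying confounder (it is autocorrelated and affects both treatment
  and outcome); only the treatment→`L1` edge is absent.  The oracle verifies
  additivity at run time (`additivity_residual`) instead of assuming it.

With π = 0.5 the effective one-step coefficients of the `L2` chain are
`auto_eff = π + (1−π)·0.3 = 0.65` and `treat_eff = (1−π)·0.5 = 0.25`, giving
true coefficients by path-tracing

```
β_2 = 0.5
β_1 = 0.5 + 0.25·0.5               = 0.625
β_0 = 0.5 + 0.25·(0.5 + 0.65·0.5)  = 0.70625
```

## Truth oracles

* **g-formula Monte Carlo** (works for any configuration): simulate `n_mc`
  counterfactual trajectories under each of the 2^K static regimes with
  treatment hard-set (confounder dynamics still respond), average Y per
  regime, and project the regime means onto the additive design with equal
  regime weights.  Common random numbers are shared across regimes and the
  projection is applied per draw, which gives a per-coefficient Monte Carlo
  SE roughly an order of magnitude below the naive independent-stream
  estimate (≈ 2·10⁻⁴ at n_mc = 400,000).
* **Closed form** (all-linear-Gaussian variant only): path-tracing with the
  carry-over–rescaled coefficients as above.  Requesting it for a binary-`L1`
  configuration raises an error rather than silently linearising.

The two oracles agree within Monte Carlo error on the linear-Gaussian
variant; this is a test, not an assumption.

## Missingness mechanisms

All mechanisms mask confounder cells only (`M = 1` means missing; treatment
and outcome are never masked).  Only MCAR masks baseline measurements;
history-dependent mechanisms start at k = 1 because their predictors are
lagged.  Cells are masked independently given the linear predictor, so
arbitrary nonmonotone patterns arise (up to 4 per time point, 2^(2K)
overall).

* **MCAR** — every maskable cell flagged with probability `expit(intercept)`.
* **MAR|A,L** — `logit P(M) = η_0 + 0.5·A_{k-1} + 0.7·L1_{k-1} + 0.5·L2_{k-1}`,
  where a lagged confounder contributes only if it is itself observed.  The
  gating keeps the mechanism exactly missing-at-random: the masking
  probability is a function of observed data alone.  (At k = 1 the lagged
  values are baseline measurements, which are always observed.)
* **MAR|A,L,Y** — adds `0.4·Y`; the end-of-study outcome influences earlier
  masks, which is possible because Y is generated before the overlay.
* **MAR|A,L,V** — adds `0.7·V`, linking missingness to the outcome only
  indirectly through the independent risk factor.
* **Constant** — a cell is maskable only when its value exactly equals the
  previous measurement; given an exact repeat it is masked with probability
  `expit(intercept)`.  Carry-forward is exactly correct by construction.
  Requesting this mechanism with π = 0 and a continuous target is a
  configuration error (exact repeats would have probability zero).
* **Differential** — per-time generation order becomes `L_k → M_k → A_k`:
  masks are drawn from the MAR|A,L model, and the treatment model drops any
  confounder masked at k (the prescriber uses only recorded values).  Among
  masked records the true confounder value is conditionally independent of
  the contemporaneous treatment; the outcome still depends on the true
  values.  Because redrawn treatments must feed back into later confounders,
  this overlay re-simulates everything downstream of treatment (keeping V
  and baseline confounders) — the one documented exception to the
  "flags-only" contract.  The true β are unchanged: they do not depend on
  the treatment-assignment model.

Intercepts are calibrated by monotone root-finding on one large simulated
panel so the realized fraction of maskable cells flagged missing hits the
scenario target: 40% (main) or 5% (secondary).  MCAR is solved analytically
(`logit(target)`).

## Estimation

* **Weights.** Pooled logistic person-time models with time-specific
  intercepts; denominator `A_k ~ time + L1_k + L2_k + A_{k-1}`, numerator
  `A_k ~ time + A_{k-1}`.  Per-time stabilized factor
  `P_num(A_k observed)/P_den(A_k observed)`, final weight = cumulative
  product.  Fitted probabilities numerically at 0 or 1 raise a positivity
  error; quasi-separation (|coefficient| > 30) is reported with the
  offending column.  Optional symmetric percentile truncation is off by
  default.
* **MSM.** Weighted least squares of Y on (1, A_0, …, A_{K-1});
  heteroskedasticity-robust sandwich variance treating weights as known
  (conservative for stabilized weights); subject-level nonparametric
  bootstrap that re-estimates weights inside each resample is available as
  the corrective.
* **Balance.** Standardized mean differences per time point are computed in
  the *unstabilized* pseudo-population (cumulative `1/P_den` weights), where
  treatment is sequentially randomized and marginal SMDs should vanish;
  stabilized weights deliberately retain the dependence on treatment
  history, so their marginal SMDs are not a diagnostic.

## The five strategies

* **Complete case** — drop subjects with any missing cell; standard pipeline
  on the remainder.
* **LOCF** — forward-fill each confounder from its most recent observed
  value; subjects missing a baseline value are dropped; the single
  imputation's uncertainty is (deliberately, as in practice) not reflected
  in the SE.
* **MPA** — person-time rows partitioned by the set of confounders missing
  at that time; one pooled (across time, within pattern) denominator model
  per pattern using only the pattern's observed confounders.  The numerator
  is a single global treatment-history-only model: the missingness pattern
  is itself affected by past treatment, so stabilizing within pattern would
  condition the pseudo-population treatment process on a post-treatment
  variable and bias the MSM (visible as a ~0.02 systematic bias at later
  time points in verification runs).  Pooling across time makes the
  no-missing-data case collapse exactly to the standard weights.  Patterns
  under `min_pattern_size` (50) person-time rows merge into the nearest
  coarser pattern.  Refuses panels with missing treatment or outcome.
* **MI** — chained equations over every partially observed confounder
  column, conditioning on V, all treatments, all confounders, and Y.  Each
  conditional is a Bayesian linear model (parameters drawn from their
  approximate posterior) with type-1 predictive mean matching (5 donors), so
  binary confounders stay binary without a separate logistic engine; the
  design also includes same-variable cross-time products and exact-equality
  indicators, which carry the sticky-trajectory signal a main-effects model
  cannot express.  Visit order is increasing missingness, 5 cycles per
  imputation, M = 10 imputations by default.  Per-panel estimates are pooled by Rubin's rules
  (`T = W + (1 + 1/M)B`, t reference with the standard MI degrees of
  freedom).  The engine is cross-checked against statsmodels' MICE
  implementation in the test suite.
* **IPMW** — missingness monotonized: a subject is censored at the first
  time any confounder is missing.  The remain probability at k is the
  product over confounders of per-cell missingness logistics fitted among
  subjects still at risk (predictors `A_{k-1}, L1_{k-1}, L2_{k-1}, V`;
  intercept only at k = 0).  The cell-level factorisation matters: censoring
  means *any* cell is missing, and a single logistic on the remain indicator
  is structurally misspecified (1 − (1−p)² is not logistic in the linear
  predictor), which produced a visible systematic bias in verification
  runs.  The stabilized missingness weight (numerator: past treatment only)
  multiplies the treatment weight; the MSM uses fully observed subjects.

## Simulation bench and problem sizes

`run_scenario` runs R replicates with per-replicate seed substreams (keyed
by replicate index, so results are invariant to execution order), analyses
each with every requested method, records failures (excluded with counts;
>10% failures aborts the scenario), and reports per coefficient: mean bias,
Monte Carlo SE of the bias (empirical SD/√R), empirical SD, mean model SE,
95% CI coverage, and the per-replicate absolute-bias distribution for
box-plot export.

Problem sizes used by the shipped acceptance suite (chosen once as the
package's standard bench): n = 10,000 subjects per replicate, R = 200
replicates for the cheap strategies, R = 40 for MI cells (one MI replicate
costs roughly 30 CC replicates), R = 100 per sample size for the n = 500
vs n = 10,000 comparison, and oracle n_mc = 400,000.

## What the generator does and does not emulate

The simulator reproduces the qualitative structure of registry data —
treatment–confounder feedback, nonmonotone missingness in covariates only,
mechanisms tied to recording practice (constant, differential) — under
conditions deliberately favourable to clean attribution: correctly specified
weight models, linear outcome, no missing treatment/outcome, no sparse or
asynchronous visits, a single continuous end-of-study outcome.  Passing
tests therefore demonstrate the *mechanism-dependent validity pattern* of
the five strategies, not their performance under model misspecification,
MNAR beyond the two structured non-MAR mechanisms, or missing exposure
data.

## Numerical choices and degenerate inputs

* One root seed per entry point; independent named substreams for data,
  masks, re-drawn trajectories, the oracle, bootstrap replicates, and
  imputations; replicate seeds are derived, below 2³¹.
* Logistic fits drop columns without variation in the fitting rows (e.g.
  `A_prev` in a design restricted to k = 0) and treat them as contributing
  zero at prediction time.
* A time point with no censoring events gets remain-probability 1 rather
  than a separating intercept.
* Identical numerator and denominator models cancel to weights of exactly
  1.0 (same floating-point path), so the weighted MSM equals unweighted OLS
  bit for bit.
* `rubin_pool` returns B = 0 and T = W exactly when a panel has no missing
  values (all completed panels identical).

## Known limitations

* The sandwich SE ignores weight-estimation uncertainty; coverage of the
  weighted estimators is conservative.  Use `bootstrap_ci` when honest
  intervals matter.
* MPA patterns are defined by the current time's missing set only; with many
  confounders the approach would need the merging fallback aggressively.
* IPMW discards subjects at the first missing cell even when later values
  are observed (monotonization); with 40% cell-level missingness this leaves
  few complete subjects and wide intervals — visible in the bench as large
  empirical SDs.
* Complete-case and IPMW point estimates carry a small O(1/n_effective)
  finite-sample bias when the number of fully observed subjects is in the
  hundreds; the bench sizes were chosen so this stays within Monte Carlo
  resolution.
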