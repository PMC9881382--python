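# Methods notes

This note records the statistical models behind `pressc`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not establish about real data.

## Synthetic cohorts

The generator emulates the statistical structure the two-stage analysis
assumes, not the assay that produces it.

**Abundance model.** Protein abundances are log-normal: log2 values are
Normal(μ_p, σ) with protein-specific baselines μ_p ~ Normal(10, 1.5) drawn
once per cohort and a common within-protein SD σ = 0.5 (log2 scale).  A
log-normal marginal matches the positive, right-skewed character of RFU
panels; the σ default is a convention, not a calibration — no public
distributional summaries of the original panels exist.  Differential
expression is an additive case-vs-control shift of `log2_fc` on the log2
scale.

**Discovery outcome coupling.** A marker with `log_hr ≠ 0` separates
progressors from non-progressors by `log_hr` SDs on the log2 scale
(point-biserial association).  The default planted discovery effects use
shifts of 2.33 and −0.99 SD, which put bagged accuracies in the 0.73–0.84
range typical of a real screen of this size.

**Validation event model.** Progression times follow proportional hazards,
S(t|z) = exp(−λ0 t^k e^η) with η = Σ log_hr · z over the standardized
planted markers; k = 1 (exponential) by default, with the Weibull shape
exposed for misspecification experiments.  λ0 defaults to −ln(0.6)/5 so the
*baseline* 5-year cumulative risk is 40%, the observed progression fraction
of the cohort being emulated; planted covariate effects raise the marginal
rate above this (Jensen), which is expected and not corrected.  Subjects
are assessed only at visit times (yearly for 5 years by default): events
become intervals (last visit before the event, first visit at/after it],
and event-free subjects at the horizon are right-censored at their last
visit.  Missingness is completely at random; the default planted validation
effects are per-SD hazard ratios 2.5 (harmful) and 0.4 (protective) — the
published per-unit hazard ratios live on a transformed concentration scale
the generator cannot reproduce, so per-SD magnitudes were fixed once in the
regime a univariate serum screen targets.

**What passing tests do not show.** The generator has independent proteins,
no batch/plate structure, no detection-limit censoring, MCAR missingness
and a correctly specified hazard model.  Passing tests demonstrate the
*procedures* behave as designed (error control, recovery, oracle
equivalence); they say nothing about correlated panels, informative
missingness, or model misspecification beyond the Weibull-shape knob.

## Discovery screen

- **Fold change** is the difference of arithmetic means of log2 values
  (log2 of the geometric-mean ratio), the standard choice for skewed
  abundance data; the filter is two-sided and inclusive at 0.585.
- **Bagging.** Bootstrap resamples are drawn from the cases only, size
  equal to the case count.  The in-bag median is multiplicity-weighted;
  for even-sized multisets it is the mean of the two central order
  statistics.  Values strictly above the median are "above"; values equal
  to it are at/below.  The classification direction is chosen per resample
  by in-bag accuracy (ties → above-median predicts progressor), the only
  rule blind to out-of-bag labels that accommodates both risk and
  protective markers; a `direction="fc_sign"` mode fixes the direction from
  the fold-change sign instead.  Resamples with an empty out-of-bag set are
  skipped; out-of-bag sets with a single class are retained (a 2×2-table
  accuracy needs no class balance).
- **A note on perfect separation.** Even a perfectly separated marker does
  not reach accuracy 1.0: the in-bag median is an order statistic lying
  inside one class, so out-of-bag members of that class on the wrong side
  of it are misclassified.  Exhaustive enumeration on 4 cases and Monte
  Carlo at 13 cases put the ceiling near 0.9 for this design; this is a
  property of median-threshold bagging itself.
- **Step-down maxT.** Labels are permuted across cases only — controls
  enter through the fold-change filter, which is outcome-blind and
  therefore fixed across permutations.  Bootstrap index sets are drawn once
  and reused across permutations (variance reduction and a large constant
  speed-up); `reuse_bootstrap=False` redraws them.  Adjusted p-values use
  the add-one estimator (1 + count)/(P + 1), so p ≥ 1/(P+1) > 0 and the
  test is valid at any P; ties at the observed statistic count as
  exceedances (with 1e−9 slack against float summation orderings).
  Monotonicity along the observed-accuracy ordering is enforced by
  successive maximization.
- **Seeding.** One master seed drives bootstrap draws and permutations via
  a single `numpy` generator; all outputs are bit-reproducible.

## Validation stage

- **kNN imputation** (k = 3): missing cells take the mean of the column
  over the k nearest rows by Euclidean distance on z-scored, mutually
  observed columns; only rows with the target column observed are
  candidates.
- **Box–Cox**: λ maximizes the profile log-likelihood on [−2, 2]
  (bounded scalar minimization of `scipy.stats.boxcox_llf`); non-positive
  inputs are shifted by 1e−6 − min(x) first.
- **Interval-censored Cox.** The baseline survival is parametrized by
  cumulative-hazard increments d_j ≥ 0 on the finite Turnbull innermost
  intervals of the pooled data, so S0(∞) > 0 is possible and right-censored
  subjects contribute S0(L)^θ.  (β, log d) is maximized jointly by L-BFGS-B
  with an analytic gradient — the same estimator as alternating
  baseline-NPMLE/Newton steps, but with a single monotone objective and a
  line search that cannot cycle; the objective trace is retained and tested
  for monotone ascent.  Bounds log d ∈ [−20, 10] keep the terminal
  increment from diverging when the last interval absorbs all remaining
  risk.  The Wald SE comes from the curvature of the *profile*
  log-likelihood (baseline re-maximized at β ± h, h refined once to ~SE/2),
  i.e. the observed information for β with the baseline as a nuisance.
  Covariates are z-scored after Box–Cox by default, so hazard ratios are
  per SD of the normalized marker.
- **Cutpoint.** Intervals are reduced to right-censored form (events at the
  interval midpoint — the least-assumption single-point summary, with
  `right_endpoint` as the alternative; censored at L).  Candidates are the
  unique covariate values between the 10th and 90th percentiles (degenerate
  strata trimmed).  S_c sums the logrank score residuals δ_i − Λ̂_NA(t_i)
  over the high group (this equals the observed-minus-expected logrank
  numerator exactly, ties included); the standardization
  q = max|S_c| / (s√(D−1)) with s² = Σ(1 − a_i)²/(D−1), a_i = Σ_{j≤i}
  1/(D−j+1) over the D event ranks, and the p-value is the
  sup-Brownian-bridge series 2Σ(−1)^{k+1}e^{−2k²q²}.  With tied midpoints
  (a visit grid guarantees them) the a_i ranking treats tied events
  sequentially; ties affect S_c only through the Nelson–Aalen increments.
  The reported threshold is the smallest covariate value of the high group,
  so "high" means x ≥ threshold; `direction` is `high_risk` when the high
  stratum has excess events.
- **Turnbull NPMLE.** Innermost intervals by the sorted-endpoint scan (R
  before L at ties, since (x, x] is empty); self-consistency EM to max mass
  change < 1e−8, capped at 10⁴ sweeps.  The survival step function drops at
  innermost right endpoints and is undefined-by-convention flat inside
  them.  Toys with a first-order-flat simplex direction (equal-gradient
  optima) converge only harmonically — brute-force comparisons use strictly
  identified configurations.
- **Generalized logrank.** Finkelstein/Sun score contributions
  u_i = (S(L)lnS(L) − S(R)lnS(R))/(S(L) − S(R)) under the pooled NPMLE
  (0·ln 0 = 0; the limit ln S + 1 when the interval carries no pooled
  mass), statistic |Σ_{group} (u_i − ū)|.  Inference is by group-label
  permutation: exact enumeration when C(n, n₁) ≤ 10,000, otherwise
  Monte-Carlo with the add-one estimator (default 2000 draws) — at n = 50
  the asymptotic χ² is not trusted.  On exactly-observed/right-censored
  data the statistic reduces to the classical logrank score.
- **Multiplicity.** Validation p-values are reported nominally (three
  candidate markers, a priori selected, is the regime this stage is built
  for); no correction column is added by default.
- **Pipeline gating.** `run_validation` dichotomizes only proteins with
  Wald p ≤ α — the two-stage semantics of "significant analytes were
  categorized".  The cutpoint is estimated on the original concentration
  scale so thresholds are interpretable (pg/mL-like units); the logrank
  scan depends on covariate ranks only, so this matches scanning the
  transformed scale.

## Problem sizes used in checks

The automated checks run at desk scale, chosen as the smallest sizes at
which each property is statistically decisive: FWER calibration uses
200–250 global-null cohorts at 200 permutations each; hazard-ratio
recovery averages 50 cohorts of n = 500 with yearly visits; the end-to-end
dichotomy pattern uses 40 cohorts of n = 50; exhaustive-enumeration oracles
run at 6–8 subjects where complete enumeration is feasible.

## Known limitations

- Independent-protein simulation: no assessment of correlated panels or
  of the screen's behaviour under strong co-expression.
- The IC-Cox Wald CI is a large-sample device; at n = 50 with ~20 events it
  is approximate (the original analyses report CIs of unstated type).
- The cutpoint p-value uses the asymptotic supremum distribution; at very
  few events it is conservative.
- The rank-based kNN-imputer variant referenced alongside the k = 3 setting
  in the source analyses is not publicly specified; plain kNN is
  implemented.
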