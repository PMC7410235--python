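# Methods

## Statistical model

The analysis treats exposure status (control vs MIA, coded 0/1 with
exposed = 1) as the outcome of a logistic regression on all candidate
variables simultaneously.  With standardized predictors the per-fit
estimator minimizes

    (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢ ηᵢ] + λ (α‖β‖₁ + (1−α)‖β‖₂²/2),

η = β₀ + Xβ, intercept unpenalized.  The general exposition of penalized
regression is usually written for the residual sum of squares; because the
outcome here is binary, the implemented objective is the penalized binomial
negative log-likelihood — the natural "Lasso logistic regression".  α = 1
by default (the elastic-net mixing is exposed but not tuned); λ is chosen
by cross-validation.

Because penalized estimators do not yield valid p-values or confidence
intervals, inference uses the non-parametric bootstrap: B row-resamples
(with replacement, unstratified; a stratified mode exists), λ re-tuned and
the model refit in each.  Per variable the pipeline reports the inclusion
probability VIP = 100·(#resamples with β̂ⱼ ≠ 0)/B, the mean odds ratio
across **all** B resamples (unselected resamples contribute exp(0) = 1 —
this is what produces the characteristic CI bounds of exactly 1 for weakly
selected variables), and the percentile CI of the OR draws.  VIP ≥ 80%
(a deliberately stringent threshold; 50% is the permissive alternative) is
the decision rule; direction is the sign of mean OR − 1.

## Preprocessing rules

* **LLOD policy.**  An analyte censored (strictly below its lower limit of
  detection) in more than 20% of assayed samples is excluded outright;
  below-LLOD cells of retained analytes are imputed at LLOD/2.  The
  censored fraction is computed per analyte over all assayed samples,
  *before* complete-case filtering, because the rule belongs to the assay
  stage, not the dataset-assembly stage.  Values exactly at the LLOD count
  as observed.
* **Complete cases.**  Subjects with any missing value in a retained
  variable are dropped (no multiple imputation — deliberately out of
  scope).
* **Standardization.**  Numeric predictors are centered and scaled to unit
  variance with divisor n (population variance), matching the convention
  of the widely used penalized-regression software family; a divisor-(n−1)
  switch exists because the choice rescales λ.  Binary variables are coded
  0/1 (Yes→1, exposed→1) and never standardized.  Standardization is
  computed once on the analysis dataset and *not* refit inside bootstrap
  resamples (a `restandardize` flag offers the alternative); within-resample
  constant columns are frozen at coefficient zero for that resample.

## Correlation screen

Pairwise Spearman rank correlations (average ranks for ties, so the
coefficient is the Pearson correlation of rank vectors) with unadjusted
two-sided p-values: the screen is descriptive, meant to document
multicollinearity, not to test hypotheses.  P-values use the classical
t approximation for n > 10 and exact enumeration of rank permutations for
n ≤ 10, where the approximation is poor.  Constant variables get NaN
correlations and are reported as undefined rather than silently zeroed.

## Solver

Cyclic coordinate descent with soft-thresholding inside a proximal-Newton
loop: each outer iteration builds the weighted-least-squares approximation
at the current fit (IRLS weights p̂(1−p̂) floored at 1e-5) and the inner
loop minimizes it coordinate-wise, iterating over the active set with
full-sweep verification.  Exact zeros come from the soft-threshold; ties at
the threshold resolve to zero so λ = λ_max reproduces the null model
exactly (intercept = logit of the event rate).  A step-halving guard
accepts only non-increasing exact objectives, so the objective trace is
monotone by construction.  Convergence is declared when the maximum KKT
subgradient violation of the exact objective is ≤ tol (default 1e-7);
non-convergence at the sweep budget (default 10,000) is flagged on the
result, not raised.  Perfect separation at λ = 0 is detected via saturated
linear predictors and reported as a warning flag.

The λ path is log-spaced over [λ_max, ratio·λ_max] with
λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/(n·max(α, 1e-3)), 100 points, ratio 1e-3,
warm-started downward.

## Cross-validation

Stratified k-fold (k = 10 default) on held-out binomial deviance; the
"min" rule picks the deviance-minimizing λ (ties to the larger λ), a "1se"
rule is available.  Which rule the original analyses of this kind used is
typically unrecorded, which is the main reason exact numeric reproduction
of any published stability table is approximate; the rule is therefore
pinned in the run manifest.  If the minority class is smaller than k, k is
reduced; if stratification is impossible outright (a single minority row in
a bootstrap resample), plain k-fold is used and single-class training folds
are handled by clipping the null-model event rate away from 0/1.  CV fold
fits run at a looser tolerance (1e-5) and a bounded sweep budget (1,000):
model selection needs prediction-level accuracy only, and the small-λ tail
of the path is quasi-separable at these sample sizes.  The fit at the
selected λ always uses the full-precision budget.

## Percentile CI

The OR draws are sorted and the (100−L)/2 and 100−(100−L)/2 percentiles
taken with linear interpolation between closest order statistics
(`numpy.percentile` default).  Interpolating on the OR scale and
exponentiating coefficient-scale percentiles agree exactly on order
statistics and differ only by the interpolation's second-order term between
distinct adjacent draws — negligible at B = 500; the tests assert the
agreement at that tolerance.

## Synthetic cohort generator

The generator draws exposure first, at the dam level (matching the causal
structure of a poly(I:C) injection experiment), then variables conditional
on group:

* **Litter structure.**  Litter sizes are 1 + Poisson(μ − 1) (mean μ,
  minimum 1) with group-specific means — defaults 3.1 (exposed) vs 3.4
  (control), emulating smaller exposed litters and ~40 vs ~27 male pups
  from 13 vs 8 dams; explicit litter-size lists allow exact pup counts.
  Each pup's `litter_size` variable is its own litter's realized size, so
  that association is structural rather than drawn.
* **Dam-level covariates** (maternal/paternal age, Δbody-mass and
  Δtemperature responses, a Bernoulli(0.4) multiparity flag) are shared by
  littermates; **pup-level phenotypes** (body mass, vocalization count,
  distance travelled, time mobile) are drawn per pup.  Effects are
  standardized mean differences (exposed − control) added on the
  standardized scale, then mapped to plausible units.
* **Cytokines** are log-normal through a single shared factor: the
  standardized log-concentration is dₖ·exposed + c·F + √(1−c²)·ε, so every
  analyte pair has population correlation c² (c = 0.55 by default, giving
  the medium-to-high inter-analyte correlations typical of serum panels).
  Per-analyte location/scale spread typical pg/ml levels over ~3 decades
  with log-SD 0.7.
* **Censoring.**  Each targeted analyte's LLOD is placed at the requested
  quantile of its marginal mixture-normal population distribution, so the
  realized censored fraction is binomial around the target.  Untargeted
  analytes get an LLOD far below the bulk (6 log-SDs).
* **Missingness** is completely at random at a configurable cell rate (the
  original missingness mechanism in studies of this design is unrecorded;
  MCAR is the neutral choice for exercising the complete-case rule).
* **Seeding.**  A master seed feeds named substreams (litters, parental,
  behaviour, cytokines, missingness), so changing e.g. the censoring spec
  does not perturb the behavioural draws.  Everything downstream
  (CV folds, resamples) derives from explicit seeds; two runs with the
  same configuration are byte-identical.

The `study_like_config` preset fixes 13/8 dams with litter sizes summing to
exactly 40/27 male pups and sets the direction pattern observed in the MIA
literature (reduced maternal mass/temperature response, smaller litters,
heavier hypoactive pups with fewer vocalizations, raised TNF-α and IL-15,
lowered IL-5 and CXCL10) at magnitudes of 0.8–1.4 standardized units —
chosen once as the kind of effect such a cohort is powered to flag.

What the generator does **not** emulate: litter-level random effects on pup
phenotypes beyond shared dam covariates, assay plate/batch effects,
non-log-normal cytokine tails, informative missingness, and any raw
behavioural signal (variables are generated at the summary level the
regression consumes).  Passing recovery tests therefore show that the
pipeline machinery finds what its own generative assumptions plant, not
that real cohorts satisfy those assumptions.

## Benchmark scenarios and problem sizes

The recovery benchmark plants one cytokine at standardized log-effect 1.25
among 15 correlated nulls (loading 0.55) in ~150 pups and runs B = 200
resamples over ten seeds; its contract is ordinal (the true predictor tops
the VIP ranking in ≥9/10 seeds and clears 80% in ≥8/10), with a matched
outcome-permutation null in which the advantage must vanish.  The
reference-scale checks run the full pipeline at 67 pups × 26 variables with
B = 100–500.  These sizes keep the full validation suite in the minutes
range on one CPU while leaving the per-run estimator identical to the
production configuration.

## Known limitations

* The 80% VIP threshold, like any stability cutoff, trades recall for
  false-positive control; variables with real but modest effects routinely
  sit at 50–80%.
* Mean ORs are shrunken toward 1 by construction (null resamples enter the
  average) and are not unbiased effect estimates.
* Dam-level covariates have an effective sample size equal to the number
  of dams; the bootstrap resamples pups, not litters, and therefore
  understates dam-level sampling variability (a litter bootstrap is a
  possible extension).
* Percentile bootstrap intervals are first-order accurate only; BCa or
  studentized variants are deliberately out of scope.
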