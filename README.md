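# stablasso

Bootstrap stability selection with L1-penalized logistic regression for
small case-control cohorts with left-censored biomarkers.

## The problem

Animal studies of maternal immune activation (MIA) — and small biomarker
studies generally — produce cohorts in which the number of candidate
predictors (parental covariates, behavioural phenotypes, a multiplex
cytokine panel) approaches the number of subjects, the predictors are
strongly inter-correlated, and assay values fall below detection limits.
Ordinary logistic regression is unstable at such low events-per-variable
ratios, and stepwise selection is unreliable under collinearity.

`stablasso` implements the alternative: fit a Lasso-penalized logistic
regression of exposure status on all variables at once, then judge each
variable by how *stably* it is selected across bootstrap resamples rather
than by a single fit.

## The method

For standardized predictors `X` (n × p) and exposure indicator `y`
(1 = exposed), the per-resample estimator minimizes the penalized binomial
negative log-likelihood

    (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢ ηᵢ]  +  λ (α‖β‖₁ + (1−α)‖β‖₂²/2),

with η = β₀ + Xβ and an unpenalized intercept; α = 1 (pure Lasso) by
default, λ tuned by stratified k-fold cross-validation on held-out binomial
deviance.  Inference is by the non-parametric bootstrap: B resamples of the
rows (B = 500 by default), λ re-tuned and the model refit in each, and per
variable j:

* **VIP** (variable inclusion probability) — the percentage of resamples
  with β̂ⱼ ≠ 0;
* **mean OR** — the arithmetic mean of exp(β̂ⱼ) over all B resamples
  (unselected resamples contribute OR = 1);
* **95% CI** — the 2.5th and 97.5th percentiles of the OR draws.

A variable with VIP ≥ 80% is reported as stably associated; mean OR > 1
means positive association with exposure, < 1 negative.

Upstream of the regression the package applies the standard multiplex-panel
hygiene: analytes below their lower limit of detection (LLOD) in more than
20% of samples are excluded, remaining below-LLOD values are imputed at
LLOD/2, subjects with any missing value are dropped, numeric variables are
standardized (divisor-n variance) and binaries coded 0/1.  A pairwise
Spearman correlation screen (unadjusted p-values) documents the
multicollinearity that motivates the penalized approach.

A synthetic-cohort generator with dam-level exposure, litter structure,
group-shifted phenotypes and a correlated log-normal cytokine block with
analyte-specific censoring provides ground-truth data for every stage.

## Worked example

```sh
stablasso run --simulate --seed 19 -B 100 -o demo_out
```

simulates the reference-scale cohort (67 pups: 40 MIA / 27 control, 26
variables), runs the full workflow, and prints:

```
report written to demo_out
flagged at VIP >= 80.0%: ['maternal_delta_temp', 'maternal_delta_mass',
'litter_size', 'usv_count_p8', 'body_mass_p15', 'CXCL1', 'IL-5']
```

`demo_out/report.txt` then holds the stability table (excerpt):

```
Group      Stage  Variable             VIP     OR     95% CI          Flag  Direction
---------  -----  -------------------  ------  -----  --------------  ----  ---------
Parental   E13.5  maternal_delta_mass  100.0%  0.182  [0.009,0.550]   *     negative
Pups'      P4     litter_size          100.0%  0.233  [0.028,0.549]   *     negative
Pups'      P15    body_mass_p15        99.0%   6.745  [1.306,35.687]  *     positive
Cytokines  P15    CXCL1                80.0%   3.148  [1.000,9.612]   *     positive
Cytokines  P15    IL-5                 93.0%   0.358  [0.014,1.000]   *     negative
Cytokines  P15    TNF-a                74.0%   4.476  [1.000,29.095]        none
```

Read a row as: the variable entered the model in that percentage of
bootstrap resamples (VIP); its mean odds ratio across all resamples gives
direction and strength (pup body mass at P15 positively associated with
MIA, litter size negatively); the bracketed interval is the percentile
bootstrap CI of the OR.  The simulated cohort's ground truth
(`demo_out/truth.tsv`) shows which flags are real — here six of the seven
flags are planted effects, CXCL1 (a correlated null sitting exactly at the
threshold) is the kind of false positive the 80% cutoff mostly, but not
always, suppresses, and TNF-α is a planted effect the cutoff missed at
B = 100.

The same workflow runs on your own data as TSV (`stablasso run --cohort
cohort.tsv --metadata meta.tsv ...`) with a metadata sidecar declaring each
variable's role (parental / pup / cytokine / outcome), kind, units and
per-cytokine LLOD; a thin adapter (`stablasso.preprocess.read_subject_spreadsheet`)
imports spreadsheets laid out like a supplementary subject table.

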