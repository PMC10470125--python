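# Methods

`gestmix` implements, end to end, the statistical pipeline of a nested
case-control analysis of gestational toxic-metal and essential-element
exposure and cerebral palsy (CP): 11 analytes measured by ICP-SFMS in
maternal whole blood (As, Cd, Cs, Pb, Hg; Co, Cu, Mg, Mn, Se, Zn), a binary
CP outcome, and a fixed adjustment set of seven covariates. Because the
underlying registry data are access-restricted, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes; every downstream stage is exercised and tested against
that generator.

## Synthetic cohort generator

**Marginals.** Each analyte is log-normal, parameterized by its published
arithmetic mean and SD via the exact moment inversion
σ² = ln(1+(sd/mean)²), μ = ln(mean) − σ²/2. Calibrating to means/SDs (not
medians) is deliberate: the mean (SD) pairs are the most complete published
summary. The medians of the real data are consequently *not* reproduced and
are never tested. Units follow the assay: μg/L for all analytes except Mg
(mg/L); nothing downstream depends on units because every analysis operates
on the ln scale after standardization or quantile scoring.

**Dependence.** A Gaussian copula: Spearman correlations are converted to
latent-normal Pearson correlations by ρ_p = 2 sin(πρ_s/6), which is exact
for the bivariate normal and carries over to the log-normal margins because
rank correlation is invariant under monotone transforms. The two published
pairwise correlations (As–Hg 0.59, Mg–Zn 0.53) ship as defaults; unlisted
pairs default to 0. A non-positive-semidefinite implied matrix is repaired
by eigenvalue clipping with a warning (or rejected, per config).

**Covariates.** Independent draws matched to the published *control-group*
margins (controls approximate the source population in a nested design):
truncated normals for maternal age, seafood intake, folate, gestational age
and BMI; Bernoullis for sex, birth-year period, parity, education, smoking
and an SGA flag. Covariate–covariate dependence is not modelled because
only margins are published.

**Outcome.** Case status follows a logistic model. Metal coefficients act
per 1 SD of the ln concentration (i.e. directly on the latent normal);
covariate coefficients per unit. Defaults mirror the direction and
magnitude of the reported associations (Cu +0.25, Mn +0.14, Hg −0.29 per
SD) and the published case/control covariate contrasts (e.g. birth period
+1.59). The source-population intercept is −4.2 (prevalence ≈ 1.5%) — higher
than the true CP prevalence (~0.2%) so that a 30,000-subject source
population reliably yields the 144 cases; the intercept is a nuisance under
case-control sampling, so this choice affects no estimand the pipeline
reports. Exactly 144 cases and 1,082 controls are drawn without
replacement.

**Assay degradation.** Three analytical rounds (proportions 0.40/0.35/0.25)
plus an external-laboratory round of 105/1226 subjects; per-round
multiplicative bias (defaults 1.0/1.1/0.9, external 1.05 — arbitrary,
overridable) and unit-mean log-normal measurement noise (CV 5%). QC
replicates (5 per round per analyte, CV 5%) measure a fixed reference
concentration under the same bias. Left-censoring: As below LOD, Cd and Co
below LOQ. The limits are not published, so defaults are the marginal
quantiles reproducing the published below-limit counts (12, 22, 33 of
1,226). Mg and Cs are missing for external-round subjects (reason
`not_analysed`); covariates get MCAR missingness at the published missing
fractions.

**What the generator does not emulate** — and hence what green tests do not
show about real data: covariate–covariate dependence, exposure–covariate
dependence (e.g. the Hg–seafood link that plausibly drives the inverse Hg
association in real cohorts), frequency matching of controls on sex and
birth year, CP-subtype heterogeneity, non-log-normal tails, and
informative (non-MCAR) covariate missingness.

## Preprocessing

Batch normalization rescales each measurement by
(pooled geometric mean of QC replicates) / (geometric mean of the
measurement's round), per analyte. The pooled mean pools *replicates*
across rounds, not round means — the two differ with unbalanced replicates.
Winsorization caps at the 1st/99th percentiles of the pooled
(cases+controls) per-analyte distribution; percentiles use linear
interpolation between closest ranks everywhere in the package. Order of
operations is batch adjustment → winsorization → ln transform: the ratio
adjustment is defined for raw concentrations, outlier capping for analysis
values. Censoring bounds for imputation are carried through the same round
factor as the measurements: a cell censored below limit L in round k is
bounded above by ln(L·f_k) and below by ln(0.1·L·f_k) (the 0.1 factor gives
the "lower ≈ 0" bound strictly positive support; configurable).

## Multiple imputation

The imputation model is a joint multivariate normal over outcome, ln
analytes and covariates (binaries 0/1), the variable list fixed to:
case status, 11 ln concentrations, maternal age, smoking, parity,
education, child sex, BMI, seafood, birth year, gestational age, folate.
Case status is always a predictor, never imputed. Estimation is EM with
missingness-pattern grouping (ML covariance, denominator n; tolerance 1e-6
on the observed-data log-likelihood, cap 500 iterations, tiny ridge for
stability). Each of the M=20 datasets is a bootstrap-EM draw: resample
rows, run EM, draw missing cells from their joint conditional normal.
Bounded (censored) cells are drawn by rejection inside their bounds with a
100-retry cap, then by a univariate truncated-normal conditional fallback;
a bound violation after fallback is a hard error. Binary cells are drawn
continuous and thresholded at 0.5 — a documented simplification of the MVN
model.

A plot-ready kernel-density overlay table (observed vs pooled imputed
values per variable) is emitted alongside the imputations as the standard
distributional sanity check; the automated tests additionally assert that
imputed values stay within the observed range ± 3 SD.

Pooling is by Rubin's rules (T = W + (1+1/M)B) with Barnard–Rubin
small-sample degrees of freedom when a complete-data df is supplied.
Likelihood-ratio statistics are pooled by the mean-statistic (D2) rule:
r = (1+1/M)·var(√d), D2 = (d̄/k − (M+1)/(M−1)·r)/(1+r) referred to
F(k, k^(−3/M)(M−1)(1+1/r)²). D2 reduces exactly to the single-dataset test
when the statistics agree, and holds its nominal level in simulation; its
null p-value distribution is, by construction, only approximately uniform
at small M — a known property of this pooling rule, asserted as level
calibration (not full-range uniformity) in the tests.

## Stability selection with permutation p-values

The selection engine is elastic-net penalized logistic regression
(mixing α = 0.9 by default) in glmnet's objective parameterization, with
per-term penalty factors so the adjustment covariates are never shrunk.
The solver is IRLS with covariance-update coordinate descent (cost
O(np² + sweeps·p²) per fit), which keeps the nested procedure tractable:
λ is chosen per fit by k-fold (default 5) cross-validated deviance on a
geometric path (λ.min rule), and a term is "selected" iff its coefficient
is nonzero at the chosen λ.

Stability selection: B bootstrap resamples of subjects (case-stratified to
preserve the case count), M imputations per resample, one CV fit per
imputed dataset; P_sel(term) = mean over resamples of the within-resample
selection fraction. Permutation p-values: K permutations of the case
labels, each rerunning a reduced stability selection (B_perm, M_perm);
p = (1 + #{null P_sel ≥ observed})/(1 + K). Full label permutation is used
— valid under the global null the procedure tests. Shipped defaults are the
study-scale settings (B=200/M=20 observed; K=1200 with B_perm=20/M_perm=10)
— the published run accountings differ between text and figure captions, so
all counts are config. Main-effect runs select at p ≤ 0.05 and
P_sel > 0.6; interaction runs (all 55 analyte×analyte plus 11 analyte×sex
and 11 analyte×education products of standardized parents, main effects
retained and still penalized) use p ≤ 0.1. BH step-up thresholds (α = 0.05
main, 0.1 interactions) are reported alongside.

## Effect models

Selected exposures enter multivariable logistic models (single-exposure
and co-adjusted), adjusted for sex, birth period, parity, education,
smoking, maternal age and seafood intake; coefficients are pooled by
Rubin's rules and reported as OR per IQR: exp(β·IQR), both on the ln scale.
Nonlinearity is tested with a natural cubic spline with boundary knots at
the 10th/90th and an interior knot at the 50th percentile of the pooled ln
exposure — this basis has 2 columns, so the spline-vs-linear LR test has
1 df (an all-interior-knot 3-df variant is available via config) — with
per-imputation LR statistics pooled by D2. Selected interactions are
refitted jointly in one pooled model and exported as plot-ready stratified
log-odds curve tables (partner at ±1 SD, or binary levels). The
sensitivity suite reruns the co-adjusted models under: term births
(gestational age ≥ 259 days), non-SGA, non-smokers, folate below/above the
observed median, no winsorization, and complete cases (no imputation);
scenarios with < 20 cases are flagged underpowered but still run.

## Quantile g-computation

Each mixture member (MixAll: all 11; MixTox: As, Hg, Cd, Cs, Pb;
MixEssential: Mn, Cu, Co, Se, Mg, Zn) is scored into quartiles (q=4,
same percentile rule; ties fall to the lower category). The core estimator
fits outcome ~ member scores + covariates per imputation;
ψ = Σ member coefficients (joint log-odds per one-quantile increase of
every member), with Var(ψ) from the full member-block covariance — not the
sum of variances, which would be wrong for correlated members — pooled by
Rubin's rules and reported as OR per quantile. Weights are computed from
the imputation-averaged coefficients and partitioned by sign, each
partition normalized to 1, so ψ is exactly the positive total minus the
negative magnitude total. Quantile cut-points are computed on the pooled
analytic sample within each imputation and may differ slightly across
imputations.

The bootstrap variant adds optional squared member scores (degree ≥ 2) and
supplied interaction terms to the conditional model, then estimates a
marginal ψ by g-computation: the population-averaged *linear predictor* at
each counterfactual joint quantile a ∈ {0..q−1} is fitted by least squares
in a. Averaging the linear predictor (rather than the logit of the average
probability) makes the variant reduce exactly to the core ψ when the model
is linear with no interactions; CIs come from a subject-level bootstrap
(resamples with zero cases are redrawn and counted), pooled across
imputations.

## Pipeline and reproducibility

`run_all` composes simulate → validate → preprocess → impute → select →
effects → qgcomp under one YAML-able config; per-stage seeds derive
deterministically from the master seed, outputs live under a
config-hash-named directory with fixed float formatting, and identical
config+seed reruns are byte-identical (wall times go to a separate log).
Every stochastic routine takes an explicit seed; nothing reads global
random state.

## Problem sizes used in the test suite

The shipped defaults are study-scale; the automated tests run the same code
at sizes chosen to keep the suite fast on one CPU while leaving each check
statistically meaningful: generator calibration at n=100,000;
stability-selection discrimination at full cohort size (n=1,226) with
B=20/M=3 and K=29 permutations over 5 replicates; null
uniformity/FDR at n=300 with K=19 over 60 replicates; spline type-I error
over 1,000 replicates at n=400; mixture recovery/coverage over 50
replicates at n=1,226. Monte-Carlo tolerances follow binomial/Fisher
standard errors at those sizes.

## Known limitations

- The generator's independence assumptions (covariates mutually
  independent; exposures independent of covariates) mean confounding
  structure is only present when configured explicitly.
- The elastic-net λ path and CV folds are the only tuning surfaces; no
  complementary-pairs stability selection or Meinshausen–Bühlmann error
  bounds.
- D2 pooling of LR tests is approximate at small M (see above).
- Binary imputation by thresholding can distort marginal prevalences when
  missingness is heavy.
- The interaction curve tables evaluate binary modifiers on the
  standardized scale of the fitted model rather than re-deriving the raw
  0/1 levels per dataset.
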