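# Methods

## Data model

A study is a `Dataset`: a subject roster (id, cohort/site, age in years,
sex F/M, diagnosis MDD/HC, intracranial volume in mm³, optional clinical
strata: age-of-onset group, antidepressant use, first vs recurrent episode)
joined to a 152-column feature matrix with an observedness mask. The
feature catalogue is fixed: 68 cortical thickness + 68 cortical surface
area (Desikan–Killiany, both hemispheres) + 16 subcortical volumes (8
bilateral Aseg structures). Files are UTF-8 CSVs; the missing-value token
is the empty string. ICV is treated as an opaque positive covariate — no
assumption about how it was estimated.

The packaged cohort table encodes 30 cohorts with exact group sizes, female
counts per group, and per-group age means/SDs; `cohort_roster()` draws an
exact-count roster from it (counts are integers from the table, ages and
ICV are sampled). Patient-only cohorts (no HC) are legal throughout;
single-subject cohorts report an age SD of 0 in summaries rather than NaN.

## Synthetic data generator

The generator is the stand-in for consortium data that cannot be shared.
Per subject j and feature v:

    y_jv = alpha_v + sigma_v * ( b_age,v (age_j - 40)/10
                               + b_sex,v male_j
                               + b_icv,v (icv_j - 1.5e6)/1.5e5
                               + theta_v mdd_j
                               + gamma_s(j),v + delta_s(j),v eps_jv )

with eps ~ N(0,1). All effects are expressed in residual-SD units so that
theta is a per-feature Cohen's d and gamma a shift in pooled-noise units.
Intercepts and noise SDs are calibrated to morphometry-like scales
(thickness 2.5 ± 0.12 mm, areas 2500 ± 300 mm², volumes 5000 ± 700 mm³).
Default covariate effects: age −0.20 SD/decade everywhere; sex (male) and
ICV +0.60/+0.40 SD for areas and volumes but only +0.05 SD for thickness,
reflecting that head size scales areas and volumes much more than
thickness. ICV itself is N(1.45e6, 1.5e5) mm³ for females and N(1.55e6,
1.5e5) for males; ages are truncated normal on [10, 90].

Site effects: gamma_sv ~ N(0, gamma_shift²) once per (site, feature);
delta_sv is log-normal around the site's delta_scale (log-SD 0.15),
truncated to [0.5, 2]. Sites sharing a `scanner_group` share 80% of their
gamma variance, which makes scanner-type classification at least as easy as
site classification — the structure behind the scanner diagnostic. A site
with gamma_shift = 0 and delta_scale = 1 is generated with exactly no site
effect, so null scenarios are exactly null.

Named scenarios: `null` (10 balanced sites, no effects), `site_confounded`
(cohort-table site structure and MDD:HC ratios, gamma_shift 0.6,
delta_scale 1.2, theta = 0), `signal_only` (d = 0.5 on 20 features spread
across all three feature classes, no site effects), `full` (both). The
0.6/1.2 magnitudes are calibrated only to reproduce the ~10-point accuracy
gap between splitting strategies qualitatively; they are not estimates of
any real consortium's site effects. Missingness: independent entry dropout
at `missing_rate`, plus block dropout where a fraction of subjects lose a
random 30–60% of features (to exercise the completeness filter).

What the generator does *not* emulate: spatial correlation between
neighboring regions, non-linear age trajectories, heavier-tailed
measurement error, and site-by-covariate interactions. Tests passing on
this generator therefore demonstrate the mechanics of the confound and its
removal, not performance on real morphometry.

## Preprocessing

Subjects providing less than 75% of the 152 features are excluded;
completeness of exactly 0.75 is retained (strict reading of "less than").
Remaining missing entries are imputed per cohort by OLS on (intercept, age,
sex), pooling diagnoses. Degenerate cohorts fall back: a constant sex
column is dropped from the design; fewer than 3 observed subjects for a
feature uses the cohort mean; a feature entirely missing within a cohort is
an error. Imputation runs once, before splitting — cohort-local and
diagnosis-blind, which trades a small within-cohort train/test information
share for a single consistent dataset.

## Fold construction

*Splitting by Age/Sex*: within each cohort, subjects are stratified by
(dx, sex) and assigned oldest-first; each subject goes to a fold with
minimal count from that stratum (with one subject of total-count slack)
chosen to keep the fold's running mean age closest to the cohort mean.
Tie-breaking follows a seeded permutation, so the assignment is
deterministic per seed. This greedy rule keeps fold sizes within ±1–2,
%female within ±2 points and fold age means within ~±2 years even for a
100-subject cohort; plain round-robin dealing on sorted age leaves ~±7-year
fold differences at that size. Diagnosis is part of the stratification, so
%MDD is near-constant across folds. Cohorts with fewer than k subjects are
dropped with a recorded reason.

*Splitting by Site*: greedy bin packing — sites sorted by size descending
(name as tie-break), each assigned to the currently smallest fold. Whole
sites are never split; the fold-size spread is bounded by the largest site.
Leave-one-site-out assignments (one per site) are provided for per-site
evaluation.

## Harmonization

ComBat is implemented from scratch in numpy. Fit: (1) per-feature least
squares of the feature on site indicators plus covariates (age, sex,
ICV/1e6), with the grand intercept defined as the site-size-weighted mean
of the site intercepts; (2) standardization by the pooled residual SD;
(3) method-of-moments empirical-Bayes hyperparameters per site —
gamma_bar_i, tau_i² across features, and inverse-gamma (lambda_i, theta_i)
matched to the mean/variance of the per-feature sample variances; (4) the
conditional posterior means for (gamma*_iv, delta*_iv) iterated to a 1e-6
relative-change tolerance (max 1000 iterations; non-convergence is an
error, never silent truncation). Apply: y* = sigma_hat (z − gamma*)/delta*
+ alpha_hat + x'beta_hat, which preserves covariate-explained variance by
construction. Diagnosis is deliberately not in the design matrix, matching
the harmonization-before-classification design; the possible cost is mild
over-correction of true group differences, which the signal-preservation
tests bound.

Agreement with the Bioconductor reference (`sva::ComBat`) is better than
1e-4 relative on a three-site fixture, and the no-EB (`direct`) variant
matches the closed-form per-site standardization to 1e-10.

Variants. `combat_gam` replaces the linear age column with a cubic B-spline
basis on 4 interior knots at training-age quantiles (built with
scipy's BSpline design matrix; the first basis column is dropped because
the basis sums to one, which the site indicators already span). The basis
is unpenalized OLS — with ~7 age columns against thousands of subjects a
roughness penalty changes little and keeps the fit linear-algebraic.
`covbat` additionally PCA-decomposes the ComBat-adjusted standardized
residuals and harmonizes the location/scale of the principal-component
scores covering rho = 0.95 of residual variance, reducing between-site
covariance differences. `direct` skips EB shrinkage (used by the
closed-form oracle).

Cross-validation semantics: harmonization is fit per CV iteration on the
nine training folds only and applied to both training and test folds. Sites
unseen in training (every test fold of the site strategy) engage the
unseen-site policy: the new site's (gamma, delta) are estimated on its own
test data under the *frozen* training standardization (alpha, beta, sigma)
and shrunk with the pooled training hyperpriors (means of the per-site
gamma_bar, tau², lambda, theta). Only training-derived quantities cross the
boundary, and diagnosis labels are never read on the apply path (tests
assert bit-identical output under label shuffling). With a single training
site the model is exactly the identity. A fitted model serializes to JSON
so that exactly what crossed the train/test boundary can be audited.

## Normative residualization and scaling

Per-feature OLS of the (possibly harmonized) features on (intercept, age,
sex, ICV/1e6) is fit on the *healthy controls of the training folds only*
(at least 5 required), then used to remove the covariate component from all
training and test data; the residuals are z-scaled by the training-set
residual mean and SD. Sex is coded male = 1; ICV is partialled from all
three feature classes including thickness. The stage order is fixed in the
pipeline: harmonize → residualize → scale → classify; a residual SD at
numerical-noise level (a constant feature) is an error naming the feature.

## Classification benchmark

Eight models: linear SVM, RBF SVM, linear SVM after PCA, linear SVM after
t-test feature selection, and logistic regression with L1/L2/elastic-net
penalties, plus random forest — all through scikit-learn, all with class
weights inverse to training class frequency. Default grids: C and penalty
ladders 1e-3…1e3 (×10), RBF gamma 1e-4…1 (×10), elastic-net mixing
{0.25, 0.5, 0.75}, PCA variance retained {0.8, 0.9, 0.95}, t-test top
{25, 50, 75}%, forest {200, 500} trees × depth {5, 10, None}. Grids are
ordered simplest-first; the inner 10-fold random-split search maximizes
balanced accuracy and ties resolve to the earliest (most regularized) grid
point; a singleton grid skips the inner loop. `model_zoo(compact=True)`
provides one-point grids for calibration studies where the grid search is
not the object of interest. Feature selection and PCA are fit inside the
training folds only.

Metrics: sensitivity TP/(TP+FN) with MDD positive, specificity TN/(TN+FP),
balanced accuracy their mean (identity holds to 1e-12 by construction), and
AUC as the Mann–Whitney rank statistic of the continuous decision score
(ties 0.5). Across-fold aggregation reports both the simple and the
fold-size-weighted mean, since site-strategy folds are unequal.

Stratified runs: sex strata filter all subjects; clinical strata
(onset/antidepressant/episodes) keep every HC plus the MDD subjects with
the matching value; subjects missing the factor are excluded from that run
only. An age-of-onset of exactly 21 would be assigned to the adult group.
`equalize_ratio` subsamples each site's majority class to 1:1 and drops
single-class sites — the experiment that shows the confound works through
the site-ratio association.

## Diagnostics

Site (or scanner-group) membership is classified with a one-vs-rest linear
SVM under the age/sex splitting and the same preprocessing order; balanced
accuracy generalizes to macro-averaged recall, reported with the 1/n_classes
chance level. `regress_covariates_then_classify` contrasts no covariate
control against regressing age/sex/ICV on the whole training folds: a
demographically driven site effect collapses, a scanner-driven one
survives. `rebalance_age_sex` subsamples all sites onto a common
age-decade × sex grid with identical cell proportions (error if sites have
disjoint support) — the negative control showing demographic balancing does
not remove a scanner-driven confound.

## Bootstrap feature weights

The point estimate is the linear SVM trained on the fully preprocessed
dataset; B resamples of subjects (599 by default, stratified by site so
cohort composition is preserved; resamples missing a class are redrawn and
counted) recompute the entire preprocessing and fit, giving per-feature
2.5/97.5 percentile intervals. Positive weight = pushes toward MDD.
Features with |point weight| > 0.1 are flagged informative. The SVM penalty
is frozen across resamples at the value chosen once on the full data
(refitting the nested search 599 times would dominate runtime without
changing the intervals); harmonization is refit inside each resample by
default, with a flag to freeze it. Percentile intervals from refits need
not bracket the point estimate; the table flags violations rather than
asserting them away. Note that at fixed C the weight *scale* of a linear
SVM grows with n, so interval widths are only comparable across sample
sizes after dividing out the weight norm.

## Orchestration and determinism

One global seed fans out via named CRC-32-keyed SeedSequence substreams
(roster, features, site-effects, folds, bench, bootstrap, …), so components
can be re-seeded independently and every pipeline is bit-reproducible:
identical config + seed gives byte-identical CSV artifacts, each row tagged
with a hash of the scientific configuration. The `sitebench` CLI exposes
simulate/preprocess/split/harmonize/run/diagnose/bootstrap/report plus a
YAML-config experiment driver.

## Problem sizes used by the verification suite

Null calibration uses 2000 subjects over 10 balanced sites with all eight
models and both strategies; the confound mechanism 3000 subjects over the
30 cohort-table sites with the linear SVM; ComBat parameter recovery 4
sites × 500; signal preservation 1200 subjects with B = 199 bootstrap
resamples. These sizes put Monte-Carlo error well inside the asserted
margins while keeping a full verification run in the minutes range on one
CPU. The expected chance-level Monte-Carlo SE of balanced accuracy at
n = 2000 is ≈ 0.011, which is the floor used when between-fold variation
(an underestimate, as folds share training data) is smaller.

## Known limitations

- Linear age effects in both harmonization (non-GAM) and residualization;
  real subcortical aging is non-linear.
- The unseen-site policy is one defensible choice; estimating a new site's
  parameters on its own test data uses test *features* (never labels) and
  slightly adapts to the test distribution.
- Nonparametric-prior ComBat, reference-batch ComBat and longitudinal
  ComBat are out of scope.
- The generator's independence of features given site/covariates makes
  multivariate site detection easier than in correlated real data; absolute
  accuracies on synthetic data are illustrative, only the qualitative
  contrasts carry over.
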