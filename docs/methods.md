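# Methods

## The problem

In a two-arm randomized trial with a binary response and many baseline
covariates (gene expression, questionnaires, imaging summaries, ...), a
treatment may help only a subset of patients — the *sensitive group* —
whose membership is expressed through treatment–covariate interactions
rather than through any single marker. `rsadapt` implements two
cross-validated procedures that classify every trial patient as sensitive
or nonsensitive and then test for a treatment effect, overall and in the
selected subgroup.

## Generative model

The simulator draws trials from a logistic interaction model: for patient
i with treatment indicator t_i and covariate row x_i,

    logit p_i = mu + lambda * t_i + sum_j alpha_j x_ij + gamma * t_i * S_i,
    S_i = sum of patient i's K sensitive covariates.

Covariates are standard normal, optionally equicorrelated at rho through a
single shared factor (x_j = sqrt(rho) z0 + sqrt(1-rho) e_j). Patients in
the sensitive subgroup (a random subset of the stated fraction, assigned
independently of arm) have their K sensitive covariates shifted upward by
`covariate_shift` (delta). Main covariate effects alpha_j default to zero.
Treatment allocation is exactly balanced by permutation.

Calibration is deterministic:

* `mu = logit(control_rate)`;
* `lambda = logit(nonsensitive_treated_rate) - mu`;
* `gamma` solves `E[expit(mu + lambda + gamma*S)] = sensitive_treated_rate`
  where S ~ Normal(K*delta, K(1-rho) + K^2 rho), evaluated by 201-node
  Gauss–Hermite quadrature and solved with Brent's method (tolerance
  1e-3 on the rate, checked after solving). gamma = 0 in the null scenario
  and whenever the target rate equals the nonsensitive treated rate.
  A target below the nonsensitive rate is rejected.

**Choice of delta.** The covariate shift controls how separable the
sensitive group is in covariate space and is not identified by the
response-rate constraints alone. It was calibrated once against the
selection operating characteristics of the reference scenario (25% control
rate, 25% nonsensitive treated rate, 70% sensitive treated rate, 10%
sensitive, n = 1000 and n = 400) over a coarse grid, giving delta = 3.5,
and is frozen at that default everywhere. With this value the per-patient
signal gamma*K*delta equals logit(TRR) - logit(control) by construction,
while larger delta means smaller gamma and hence less response noise
leaking into the per-covariate fits.

What the generator does *not* emulate: non-normal covariate distributions,
heteroscedastic or structured (block) correlation, covariate-dependent
allocation, and any departure of the real unpublished generator from this
reconstruction. Passing simulation checks therefore validate the methods
under this model family, not under arbitrary real data.

A second generator, `simulate_start_like`, produces pragmatic-trial-like
tables (default 670 patients, 86 covariates of mixed type — binary
prevalences, bounded integer questionnaire scores, continuous measures on
heterogeneous scales — ~43% event rate, ~2% missing cells). A planted
subset of covariates carries treatment interactions of standardized
per-covariate size `interaction_strength/sqrt(n_interacting)`; an
arm-level offset is solved numerically so the *marginal* treatment effect
is zero by construction. It exercises preprocessing, prefiltering and
permutation inference on realistic inputs; it makes no claim to reproduce
any particular trial's joint distribution.

## CVRS: cross-validated risk scores

For r-fold cross-validation (default r = 10, folds stratified by arm so
small trials cannot produce single-arm training folds):

1. On each training set, fit one logistic model per covariate and keep the
   treatment–covariate interaction estimate beta_j. The default variant
   for simulated data is interaction-only (`logit p = mu + beta_j t x_j`),
   matching the generating mechanism; variants with main covariate and
   main treatment effects are available and are the right choice for real
   data whose covariates have nonzero means (otherwise the arm offset
   loads onto every interaction term).
2. Score each held-out patient: RS_i = sum_j beta_j x_ij (a
   compound-covariate / polygenic-score construction).
3. Split the held-out scores into two clusters with 2-means; the cluster
   with the larger center is sensitive (the only orientation consistent
   with beta-weighting, where larger scores mean larger predicted
   benefit). Labels are pooled across folds, so each patient is classified
   exactly once.

In one dimension the k = 2 within-cluster-sum-of-squares optimum is a
contiguous split of the sorted values, so step 3 is computed *exactly* by
scanning the n−1 sorted cuts with prefix sums (ties at the first
minimizing cut; scores centered before accumulation for numerical
stability). This replaces restart-based heuristic k-means with its exact
optimum; the test suite verifies equality with both a brute-force split
enumeration and sklearn's KMeans with 50 restarts. If all scores in a fold
coincide the fold is degenerate: everyone is labelled nonsensitive and the
fold is flagged.

**Nested variant.** To check that clustering *test* scores does not leak
information, the nested variant estimates cluster centers in an inner
r-fold layer on each training set (one sorted center pair per inner fold,
averaged), then assigns outer held-out scores to the nearest averaged
center. If every held-out score falls nearest one center (an empty
cluster), the fold falls back to plain 2-means on the held-out scores and
is recorded.

**Prefiltering and the threshold scan.** With many covariates, covariates
can first be screened by the interaction p-value (strictly below a
threshold), computed *within each training fold only*, preserving
cross-validation validity. `threshold_scan` profiles the
treatment-by-sensitivity interaction p-value over a threshold grid
(default {0.01, ..., 1.00}), holding the fold plan fixed, and returns the
minimizing threshold; thresholds that empty some training fold are marked
not evaluable and excluded.

## CVASD: cross-validated adaptive signature design

The reference method fits, per covariate, `logit p = mu + lambda_j t +
beta_j t x_j` on the training set; covariates with interaction p < eta
form the signature, and a held-out patient is sensitive when the predicted
odds ratio `exp(lambda_j + beta_j x_j)` exceeds R for at least G signature
covariates. The tuning triple (eta, R, G) is selected per outer fold from
a candidate list using one inner training/validation split (validation
fraction 1/10, stratified by arm): the candidate whose inner sensitive
group gives the smallest two-sided Fisher p-value for the arm difference
wins; degenerate candidates (empty or single-arm group) score p = 1 and a
fully degenerate slate falls back to the first candidate with a warning.
The default candidate grid is the six published triples
{(0.01,2,3), (0.02,3,2), (0.03,4,1), (0.5,1.5,2), (0.6,1.6,2), (0.7,1.7,1)}.
Because the odds-ratio rule is one-directional, real-data covariates are
first oriented by `sign_transform` (columns with negative full-data
interaction coefficients negated); the risk-score method needs no such
transform. Computing the transform on the full data mirrors the published
analysis but is a potential (mild) leak; it can be skipped.

## Numerical core

Per-covariate fits are solved by a batched Newton–Raphson over all J
design matrices simultaneously (exact score and observed information;
linear predictors clipped at ±30; likelihood-guarded step halving for
steps larger than 1). Covariates whose fit fails to converge, has a
singular information matrix, or runs past |coef| = 10 (separation) are
refit with a Firth bias-reduced (Jeffreys-penalized) fit, and capped at
|coef| = 10 as a last resort, with flags recorded. Wald p-values come from
the inverse observed information. Agreement with statsmodels GLM is
asserted in the tests (1e-12 on coefficients, 1e-6 on p-values).

## Testing layer

* Overall test: two-sided chi-square for the 2×2 arm-by-response table
  with Yates continuity correction (scipy's convention matches the
  classical capped correction); degenerate tables give p = 1, flagged.
* Subgroup test: two-sided Fisher exact test among the selected patients
  (hypergeometric-summation two-sidedness); empty or single-arm subgroup
  gives p = 1.
* Split-alpha rule: the design is positive when the overall test rejects
  at alpha1 or the subgroup test at alpha2 (defaults 0.04/0.01, i.e. 80%
  / 20% of alpha = 0.05); both are configurable.
* Interaction test (real-data path): Wald p-value of the
  treatment-by-sensitivity term in a binomial-logit GLM (statsmodels).
* Permutation inference: treatment labels are permuted (responses and
  covariates fixed), the *entire* pipeline re-run per permutation, and
  p = (1 + #{permuted p ≤ observed p}) / (1 + B), bounded in
  [1/(B+1), 1]. The tuned variant re-runs the full threshold scan per
  permutation and compares minimized values, so min-p selection is part
  of the null. The permutation RNG is independent of the fold RNG.
  At the published scale (B = 2000 with a 100-point grid) the tuned
  variant is expensive by design; tests exercise it at small B.

## Simulation harness

`run_replicate` keys the dataset RNG stream by (study seed, replicate
index) and the fold RNG additionally by method, so CVRS and CVASD are
compared on identical trials. Operating characteristics aggregate:
empirical power of each test and of the design, selection sensitivity and
specificity against the simulated truth, and the observed response
proportion among classified-sensitive treated patients. Replicates with no
selected treated patients contribute p = 1 to the tests and are excluded
from the response-rate mean (their count is reported). Under the null
scenario no truth labels exist; sensitivity/specificity are scored against
a random 10% pseudo-truth per replicate so that an uninformative ~50/50
classifier scores 0.5.

Problem sizes: the packaged studies use 200 replicates for power/selection
scenarios and 500 for the null error rates (n up to 1000 patients, 100
covariates, 10-fold CV) — enough for ~0.02–0.03 Monte-Carlo standard
errors on proportions.

## Known limitations

* Binary outcomes and two sensitivity classes only.
* The generator's delta is a reconstruction: scenarios with very small
  sensitive fractions (~5%) are the most sensitive to it — 2-means tends
  to over-select when the true cluster is tiny, diluting the estimated
  subgroup response rate relative to the published value for that cell.
* Imputation means are computed on the full table before cross-validation
  (mirroring the published real-data analysis); a fold-safe alternative is
  exposed (`preprocess_frame(..., impute=False)` plus `impute_means` per
  training fold).
* The CVASD candidate grids actually used for the published simulation
  tables are not public; CVASD results here depend on the supplied grid.
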