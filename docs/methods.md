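# Methods

This note documents the models and procedures implemented in `metabosurr`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic validation does and does not demonstrate.

## The surrogate model

Each binary clinical variable `c_k` is modelled by penalized logistic
regression on the z-scaled metabolite panel `m`:

    pi_k = Pr(c_k = 1 | m) = 1 / (1 + exp(-(beta_0 + beta' m)))

fitted with the elastic-net penalty `lambda * (alpha * ||beta||_1 +
(1 - alpha)/2 * ||beta||_2^2)` on the mean binomial deviance. The mixing
parameter is fixed at `alpha = 0.5`; the penalty weight `lambda` is the only
tuned hyperparameter. The fitted posterior probability `pi_k` is the
*metabolic surrogate* of the variable — a continuous, uncalibrated stand-in
for the dichotomous original. No probability calibration is applied: in the
intended use case (imputing wholly missing variables) there is no labelled
subsample to calibrate on, and the surrogate's ordering, not its absolute
level, carries the information.

Fits are performed with scikit-learn's saga solver, warm-started along a
descending `lambda` path. The mapping `C = 1 / (n * lambda)` makes
scikit-learn's sum-loss objective equal (up to the factor `n`) to the
mean-loss elastic-net objective stated above. One numerical detail: when the
penalty zeroes every coefficient, the profile optimum of the unpenalized
intercept is analytically `logit(prevalence)`, and the code sets it exactly,
because at extreme penalties the solver's relative-tolerance stopping rule
leaves the (then numerically weightless) intercept unconverged.

### Penalty selection

- Grid: `n_lambda` (default 100) values log-spaced over 4 decades downward
  from `lambda_max = max_j |x_j'(y - ybar)| / (n * alpha)`, the smallest
  penalty at which the KKT conditions zero every coefficient.
- Criterion: minimum mean held-out binomial deviance ("lambda-min" rule)
  over an inner loop of stratified 5-fold CV with 5 repetitions (defaults).
- Fold partitions are drawn independently per repetition; all fold RNGs
  derive from the `TrainConfig` seed, so training is bit-reproducible.

### Evaluation

Two procedures, both rerunning the *entire* inner selection inside each
training split so that no held-out data influences `lambda`:

- **Double cross-validation** — an outer loop of stratified 5-fold CV
  (5 repetitions by default); the reported score is the mean held-out AUC.
- **Leave-one-biobank-out (LOBOV)** — each cohort in turn is excluded from
  training and scored as the test set; the summary is the mean AUC weighted
  by held-out cohort size. A held-out cohort with only one class is skipped
  with a warning rather than scored 0.5: an undefined AUC is not evidence.
  A model is conventionally called adequate at AUC > 0.7.

AUC is computed by the Mann-Whitney rank identity with ties counted 1/2,
and is verified in the tests against exhaustive pairwise counting.

### Relative importance

For model inspection, coefficients are scaled per model by the sum of their
absolute values, making rows sum to 1 in absolute value and the scaling
invariant to positive rescaling of the coefficient vector. With mixed-sign
coefficients a plain signed sum could be near zero and explode the ratios;
the signed-sum variant remains available behind a flag.

## QC and preprocessing

Sample filters run in a fixed order, each sample being removed at the first
rule it violates: (1) more missing marker values than a ceiling (default 0);
(2) one or more zero concentrations; (3) any marker further than 5 SD from
the column mean. The mean/SD of rule (3) are computed on the survivors of
rules (1)-(2) — contaminated cells should not distort the scale they are
judged against — with a switch to compute them on all input samples instead.
Zero-variance columns flag nothing. The sample SD (n-1) convention is used
throughout.

The missing-value ceiling and subsequent imputation coexist deliberately:
with a ceiling of 0 nothing remains to impute, but a nonzero ceiling admits
samples with a few missing cells, which are then completed by NIPALS —
an apparent redundancy kept configurable because published pipelines have
applied both a missing-sample filter and residual imputation.

NIPALS imputation estimates principal components by alternating score and
loading regressions restricted to observed cells, then replaces missing
cells by the low-rank reconstruction. Because one-pass centring by observed
column means is biased when missingness shifts a column's mean, the
implementation iterates fill / recentre / refit to a fixed point; on exactly
low-rank matrices this recovers deleted cells to numerical precision (the
tests require 1e-6 on rank-1 matrices). The component count defaults to the
number explaining 95% of the variance of the complete rows, capped at 10;
missingness above a configurable ceiling (default 5%) is refused, as sparse
missingness is the method's domain of validity. Imputation never alters
observed cells.

Z-scaling stores per-marker mean/SD so that new samples (e.g. an external
cohort being projected) are mapped onto the training scale. The default
policy scales once, globally, before training — matching common practice on
pooled panels — with the stricter per-training-fold option available where
the small leakage of global scaling matters.

## Clinical variable derivation

All thresholds live in a versioned YAML file, not code. Each dichotomous
variable is TRUE when all of its conditions hold, FALSE when a condition
fails on complete inputs, and *missing* whenever any required input is
missing — never silently FALSE. Boundary semantics follow the printed
comparators exactly (`>=`/`<=` inclusive, `>`/`<` strict; age bands
`< 45`, `45 <= age < 65`, `>= 65` are mutually exclusive and exhaustive).

Composite variables:

- **LDL cholesterol** (Friedewald): `LDL = TC - HDL - TG/2.2` (mmol/L),
  returned missing above the equation's validity bound TG > 4.5 mmol/L.
- **eGFR** (2009 creatinine CKD-EPI): `141 * min(Scr/k,1)^a *
  max(Scr/k,1)^-1.209 * 0.993^age * 1.018[female]`, `k = 0.7/0.9` and
  `a = -0.329/-0.411` (female/male). The race coefficient is off by default
  (the populations modelled are described as ethnically homogeneous) but
  available as a flag. Creatinine units must be declared — no autodetection.
- **Obesity**: BMI >= 30 AND waist >= 102 cm (men) / >= 93 cm (women).
- **High blood pressure**: systolic >= 140 AND diastolic >= 90 mmHg.
- **Low haemoglobin**: <= 6.67 mmol/L (men) / <= 7.62 mmol/L (women).

Three threshold choices are implemented as printed in the source table even
though they differ from common conventions, and are flagged here: the female
waist cutoff of 93 cm (88 cm is the usual criterion), a female low-Hgb
threshold above the male one, and high blood pressure as the AND rather
than OR of the two pressures (an OR variant sits behind a flag).

## MetaboWAS

Metabolite distributions are right-skewed, so each marker is first mapped
through the rank-based inverse normal transformation
`x_i -> Phi^-1((r_i - 3/8) / (n + 1/4))` (Blom offset, average ranks for
ties); the output depends on the input only through its ranks. Each
transformed marker is then regressed on the phenotype plus covariates by
OLS; the phenotype coefficient with its t-based p-value is the reported
effect (metabolite as response — the direction used for the published
diabetes associations; a logistic phenotype-as-response variant is flagged).
All markers share one design matrix, so the regressions are solved
vectorized through a single QR factorization; the tests verify equality
with per-marker normal-equations estimates to 1e-8.

Multiplicity uses Bonferroni over the *effective* number of tests: the
smallest number of principal components of the RIN-transformed, standardized
marker matrix explaining >= 99% of its variance, giving the threshold
`0.05 / k_eff`. `k_eff` is recomputed for each analysis dataset — the
published value of 40 is that study's dataset-specific count, not a
constant. On the synthetic panel (weaker between-class correlation than a
real lipoprotein ladder) `k_eff` is typically ~52-54 of 56.

The confounder-substitution analysis runs the same MetaboWAS under two
adjustment sets and reports paired estimates, their squared correlation,
sign agreement, and the 2x2 significance contingency with raw counts first;
discordance rates (A-only / A-significant; B-only / A-nonsignificant) are
secondary because rate definitions vary across reports.

## Survival association

Per-surrogate Cox proportional-hazards models use follow-up time as the
time scale, Efron tie handling, and — because the elderly validation
cohorts are family-based — Huber sandwich standard errors grouped by family
(lifelines `cluster_col`). Surrogates enter per 1 SD of their observed
distribution so hazard ratios are comparable across surrogates (the unit is
recorded in the output). Left truncation, competing risks and time-varying
effects are out of scope. P-values are BH-corrected separately within each
selection stratum (all / men / women) at FDR < 0.05; the strata use
disjoint sample sets whose union is the unstratified set.

The stepwise search starts from the model containing all candidate
surrogates plus the fixed covariates (age, and sex when unstratified), and
at each round takes the single add-or-remove move with the largest decrease
of the partial-likelihood AIC (`-2 logL + 2k`), stopping when no move
decreases it; fixed covariates are never dropped. AIC uses the naive
likelihood — AIC is a likelihood construct — while the final reported
coefficients carry cluster-robust errors, and per-term p-values are included
in the trace for inspection. No p-value stopping rule is layered on top of
AIC: a second criterion without a stated cutoff is not reproducible.

## The synthetic-cohort generator

The generator emulates the structure of a multi-biobank 1H-NMR resource so
that every stage is testable without access-restricted data.

- **Markers.** 56 named markers in seven biochemical classes (lipoprotein
  lipid totals, fatty acids, amino acids, glycolysis-related, ketone
  bodies, inflammation, fluid balance). Log-concentrations load on one
  latent Gaussian factor per class (loading 0.35) plus idiosyncratic noise
  (SD 0.25), giving within-class correlations ~0.6 and marker CVs of
  roughly 35-50% after exponentiation; baseline log-means span 0.05-3
  concentration units.
- **Phenotypes.** Labels are drawn at the target prevalence (default 0.25);
  the liability is N(0,1) in controls and N(d,1) in cases, so the oracle
  AUC of the true liability is exactly `Phi(d / sqrt(2))` — the
  equal-variance binormal identity, verified by Monte Carlo in the tests.
  The liability couples into the markers through a weight vector (demo:
  12 markers at |weight| 0.3, two-thirds positive). This coupling attenuates
  what any marker-based predictor can achieve by a few hundredths of AUC
  below the oracle, which is visible in the recovery results.
- **Cohort structure.** Per-cohort, per-marker batch offsets (additive on
  the log scale, SD 0.15) and gains (multiplicative on the centred log
  signal, SD 0.15). A finding from building the gap experiment: *additive
  offsets alone cannot make LOBOV underperform CV*, because a per-cohort
  constant shift leaves the within-cohort score ranking — hence the
  held-out AUC — untouched. The component that reproduces the
  CV-over-LOBOV optimism is per-cohort **prevalence heterogeneity**
  (`prevalence_spread`, a normal jitter of the cohort-level prevalence):
  combined with cohort marker signatures, pooled CV can exploit cohort
  identity as a label proxy while a held-out biobank's signature is new.
  The gap experiment therefore enables `prevalence_spread = 0.10` together
  with the batch components; recovery and null checks run at spread 0.
- **Artifacts.** Missing cells, zeros and outliers are injected on
  disjoint samples (so each corrupted sample is attributable to exactly one
  QC rule) with the exact cell mask recorded; outlier cells are displaced
  7-10 SD above the column mean computed without the cell.
- **Survival.** Exponential proportional-hazards event times with linear
  predictor `sum(log HR * covariate)`, multiplied by a gamma frailty
  (mean 1, variance 0.5 by default) shared within families, and
  administrative censoring at the empirical quantile matching the target
  censoring fraction. Note that shared frailty *attenuates the marginal
  Cox estimate* (high-frailty subjects die early, selecting low-frailty
  survivors): a conditional HR of 2 fits marginally near 1.5 at frailty
  variance 0.5. Hazard-ratio recovery is therefore checked without
  frailty, and frailty is switched on where clustering itself (robust vs
  naive SEs, CI coverage) is the target.

### What the generator does not emulate

Real inter-metabolite covariance (the generator's block-diagonal factor
structure is far simpler than a lipoprotein subclass ladder, which is why
its `k_eff` is higher than a real panel's), real marginal concentration
scales, assay drift over time, informative missingness, and non-proportional
hazards. Passing tests demonstrate that the *procedures* are implemented
correctly and recover planted truth under the stated model — not that real
panels meet these assumptions. One visible consequence: the 5-SD rule on
raw log-normal concentrations trims ~10% of samples as natural tail at
these CVs, several times more than on real panels whose tails are lighter.

## Problem sizes and runtime choices

Library defaults keep the full procedure (5x5 inner and outer repetitions,
100-point penalty grid). The demo and validation runs use desk-scale
settings chosen as this package's own working sizes: 10 cohorts x 500
samples, a 30-point grid with 1 inner and 1 outer repetition for recovery;
6 cohorts x 150 with an 8-point grid over 20 replicate seeds for the
CV-LOBOV gap; 200 simulated datasets for family-wise error; 100 replicates
for robust-CI coverage. All stochastic steps derive their seeds from a
single integer.

## Numerical conventions

- Sample SD (n-1) everywhere; zero-variance columns raise in `zscale` and
  are inert in the outlier rule.
- Ties: average ranks (AUC, RIN); Efron approximation (Cox).
- `effective_tests` bounds `k_eff` by the numerical rank (eigenvalue
  tolerance `lambda_1 * max(n,p) * eps`).
- Degenerate inputs fail loudly: single-class labels, constant surrogates,
  zero events, collinear designs and absent markers all raise with the
  offending names in the message.
- TSV I/O is UTF-8, tab-separated, `NA` for missing, floats at repr
  precision and parsed with `float_precision="round_trip"`, so a write/read
  cycle is bit-exact.
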