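# Methods

## Scope and data model

The package analyses a cohort of patients with a binary coronary artery
disease (CAD) label against a panel of immune-cell subset proportions
measured by mass cytometry. CAD status is never stored: it is derived as
Gensini score > 0, so a patient with entirely normal coronary arteries
(score 0) is CAD− and any positive stenosis burden is CAD+. Proportions
are kept on the percent scale throughout, because the effect size of
interest is the odds ratio per one-percentage-point increase in a subset.
Each subset is defined against a denominator: either total live cells
(the 11 major populations) or its parent population (the remaining 71
marker-defined subsets). The only compositional constraint enforced is
that the %total values of the major populations sum to at most 100 per
patient.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, at the
study's scale: a discovery cohort of 117 patients and a validation cohort
of 58.

* **Demographics.** Age ~ truncated Normal(61, 12²) on [30, 95] years;
  sex Bernoulli(0.49 male); BMI ~ Normal(27.1, 4.8²).
* **Disease label.** logit P(CAD) = 0.45 + 1.0·(age−61)/10 + 1.0·male.
  The intercept and slopes were calibrated once, by numerical integration,
  to reproduce a marginal prevalence of ≈ 0.68 with CAD+ patients about a
  decade older (≈ 64 vs 54 years) and more often male (≈ 56% vs 36%) —
  the margins of the motivating cohort.
* **Subset proportions.** Each subset k is logit-normal:
  p = 100·expit(z), z ~ Normal(μₖ + δₖ·1[CAD] + γₖ·(age−61)/10 +
  batch·1[validation], σₖ²). The logit-normal respects the [0, 100]
  bounds and makes planted effects analytically tractable; nothing in the
  motivating data dictates a distributional family. For the 18 headline
  subsets, (μₖ, σₖ) and the total CAD-associated logit shift are set from
  the published CAD−/CAD+ group means and SDs via the delta method. The
  shift is then split between δₖ (direct CAD effect) and γₖ (age trend)
  by population: conventional CD4/CD8 T-cell subsets route 70% of it
  through age (so age/sex adjustment attenuates them), while Treg, B-cell
  and pDC subsets carry 85% directly (so adjustment leaves them largely
  intact) — mirroring the attenuation pattern the adjusted models are
  meant to expose. The implied per-percent odds ratios span ≈ 0.84–1.25
  (and ≈ 2.8 for the sub-percent proliferating-B subset, where one
  percentage point is a large relative change). The 64 filler subsets
  have cycling baselines between 3% and 55%, no CAD effect, and mild
  alternating age trends.
* **Batch effect.** The validation cohort receives an additive logit
  shift (default −0.2) on every subset, so raw levels are not comparable
  across cohorts but within-cohort fold changes keep their direction —
  the situation the concordance analysis is designed for.
* **Risk factors and medications.** Drawn with age-dependent prevalences
  (logistic in age, baselines at the cohort margins: hypertension 43%,
  diabetes 7%, hyperlipidaemia 53%, statin 33%, ...). Gensini scores for
  CAD+ patients are log-normal with median 7.5.

`planted_or` reports the large-sample per-percent OR implied by a
configuration: covariates are drawn on a fixed integration stream, each
draw is split into CAD−/CAD+ branches weighted by the label-model
probability, and the population logistic slope is solved from the
weighted score equations. When δₖ = γₖ = 0 the subset is independent of
the label by construction and the function returns exactly 1.

**What the generator does not emulate:** gating noise and panel drift,
correlations between subsets beyond those induced by age and CAD,
missingness, repeat measurements, or any relationship between the
magnitude of the Gensini score and the immune profile. Passing tests
demonstrate that the statistical machinery recovers what was planted
under these idealised conditions — not that the biological effects are
real or that the signature would transfer to another scanner or panel.

## Statistical stages

* **Contingency tests.** The 2×2 χ² is the uncorrected Pearson statistic
  (no Yates correction): only the uncorrected form reproduces the
  published baseline-characteristics p-values (e.g. hypertension 0.013
  uncorrected vs 0.022 corrected). The default applies χ² to every
  categorical trait; the expected-count rule (Fisher's exact when any
  expected cell < 5) is available as a config option, and routes e.g. a
  diabetes-like table to Fisher p = 1.0 where χ² prints 0.640. The
  two-sided Fisher p sums hypergeometric probabilities ≤ that of the
  observed table, comparing pmf values with a relative tolerance of 1e-7.
  The rank-sum test uses mid-ranks, exact enumeration for combined n ≤ 12
  without ties, and the tie-corrected normal approximation with
  continuity correction otherwise.
* **Logistic panel.** Maximum likelihood by Newton iteration
  (statsmodels), covariance from the inverse observed information, Wald
  CIs and p-values (the published intervals are consistent with
  exp(β ± 1.96·se) symmetry). Age enters in years, untransformed; sex as
  a male indicator. Separation is flagged when a standardised coefficient
  exceeds 20 in magnitude; zero-variance subsets are reported untestable
  rather than dropped. No multiple-testing correction is applied by
  default, matching the presentation of per-subset panels in this
  literature; a Benjamini–Hochberg column is available behind a flag.
* **Concordance.** Fold changes are ratios of arithmetic group means,
  computed within each cohort; the correlation is computed on the raw
  fold-change scale by default (as plotted in this literature), with a
  log option. Undefined fold changes (zero denominator mean) are excluded
  pairwise and counted. By default the test runs over the subsets flagged
  significant in the discovery panel.
* **Classifiability.** Stratified fold assignment (prevalence ≈ 0.68
  makes unstratified 5-folds occasionally single-class); folds are
  redrawn (up to 10 times, logged) if a training split lacks a class.
  Per fold: features are screened on the training split by Mann–Whitney
  AUC, ranked by |AUC − 0.5| (an AUC of 0.2 is as informative as 0.8;
  ranking by raw AUC is a config option), standardised with training
  statistics, and fit with an L1-penalised logistic model whose penalty
  is chosen from a 50-point log-spaced grid by minimum mean deviance in
  an inner stratified 5-fold CV. The intercept is effectively
  unpenalised (the usual lasso convention), so at maximal penalty the
  model collapses to the majority-class predictor. Held-out predictions
  threshold the probability at 0.5. A patient's classifiability is the
  fraction of repeats with a correct held-out prediction; its mean over
  patients equals the overall repeated-CV accuracy by construction.

  A known property of this screen-then-fit procedure: on pure-noise
  features the mean classifiability sits a few points *below* the
  majority-class rate, because the AUC screen hands the inner CV the most
  spuriously label-correlated features, which then anti-generalise on the
  held-out fold. The screen never sees held-out labels, so accuracy is
  never inflated above the baseline; the test suite asserts exactly this
  one-sided behaviour.
* **Modifier regression and sub-cohort.** Classifiability is regressed
  on each clinical covariate separately (simple regressions; a joint
  model would conflate collinear risk factors), ranked by the p-value of
  a non-zero slope. The sub-cohort rule is age ≥ cutoff (default 55,
  boundary inclusive); a helper scans integer cut-offs for the one
  maximising the between-group difference in mean classifiability,
  subject to a minimum group size of 10.
* **SVM signature.** RBF kernel with cost C = 1 and γ = 1/(p·var) on
  standardised features (both exposed in config); scores are signed
  decision values — ROC and AUC only need a ranking, so no probability
  calibration is attempted. Per-fold ROC curves are averaged vertically
  (mean TPR on a 0–1 FPR grid with step 0.01); the mean AUC is the
  arithmetic mean of per-fold rank-formulation AUCs. For external
  validation the model is trained on the whole discovery sub-cohort with
  a fixed feature list (the subsets flagged significant by the
  differential panel) and standardisation learned on discovery only.
  Feature-set comparisons (subsets vs age+sex vs combined) share fold
  assignments and seeds so the AUCs are directly comparable.
* **Decision boundary.** PCA is computed on the standardised discovery
  sub-cohort by SVD, keeping two components with the sign convention
  that the largest-magnitude loading is positive; validation points are
  projected with discovery loadings and standardisation only. A
  feed-forward net (2 inputs → 16 tanh units → linear outputs, lbfgs,
  seeded) maps the PC plane back to standardised feature space; if its
  training loss cannot come within 1.5× the exact rank-2 linear
  reconstruction's, the linear inverse (loadingsᵀ) is used instead, with
  a warning. The grid (default 200×200) covers all projected points with
  a 5% margin. The boundary map is a diagnostic visualisation, not a
  deployment model.

## Determinism and numerics

All randomness flows from a single integer seed through numpy
SeedSequence spawning; repeated runs with the same seed, config and
inputs produce byte-identical outputs (asserted in the test suite).
Logistic convergence uses tol 1e-10 with a 100-iteration budget;
liblinear lasso fits are seeded with tol 1e-6; extreme penalty-grid
endpoints occasionally fail to converge and are simply never selected by
the deviance criterion. Ties in AUC screening break by original column
order; clustering uses complete linkage with Euclidean distance (merge
order between exactly tied dissimilarities follows the linkage
implementation).

## Problem sizes in the test and acceptance runs

Simulation-backed checks run at reduced replication so the whole suite
completes quickly on one CPU: planted-OR recovery uses 60 replicates of
n = 2000 (acceptance script: 30); the null type-I check 200 replicates of
an 8-subset panel at n = 117; the planted age-modifier recovery 20
replicates of the full 117 × 82 problem with 5-fold × 10-repeat CV and an
8-point penalty grid; the null-signature check 20 seeds. The statistical
conditions (cohort sizes, effect sizes, prevalences) are unchanged from
the defaults described above.

## Known limitations

* Wald intervals can be poor for near-separated subsets (e.g. sub-percent
  proportions with large effects); profile-likelihood intervals are not
  implemented.
* The fold-change concordance treats subsets as independent observations;
  correlated subsets overstate the effective n of the t test.
* The age cut-off scan is a between-group mean-difference heuristic, not
  a change-point estimator with inference.
* The classifiability statistic depends on the base rate; comparisons
  across cohorts with different prevalences should not be read as model
  quality differences.
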