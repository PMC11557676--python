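# Methods

This note documents the models, rule sets, numerical choices and the
synthetic-cohort calibration behind `taigrade`. It is written for a reader
who wants to know exactly what the package computes and what its passing
tests do and do not demonstrate.

## Anatomical grading of traumatic axonal injury

TAI lesions are registered at 58 predefined locations (laterality counted:
27 paired structures × 2 sides + 4 midline structures) on three MRI
sequences (FLAIR, DWI, T2\*GRE/SWI). The packaged ontology
(`data/ontology.csv`) assigns each location to one of ten region groups
(hemispheric white matter, cerebellum, corpus callosum, basal ganglia,
thalamus, posterior-limb internal capsule, mesencephalon, pons, medulla,
cerebellar peduncles). The true supplementary location list of the source
cohort is not public; the packaged list is an anatomically standard
reconstruction and is a plain data file — substituting a different list
with the same columns requires no code change, and the gradings depend
only on region-group membership.

Feature extraction reduces a patient's annotations to region-level flags
and totals. A region group is *involved* if any of its locations is
present on **any** sequence; it is *bilateral* if involved on both sides
(the sequences may differ between sides — presence is registered per
location across sequences, not per sequence). *Unilateral* means involved
on exactly one side. The brainstem is bilateral iff any single segment
(mesencephalon, pons or medulla) is itself bilateral; a left-pons plus
right-mesencephalon pattern counts as unilateral involvement of two
segments, not a bilateral brainstem.

Gradings are declarative rule sets (YAML data files): an ordered list of
(grade, predicate) pairs over the feature flags; the final grade is the
highest satisfied rule, and patients without TAI receive the rule set's
`no_tai_grade`. Shipped rule sets:

| rule set | tiers | notes |
|---|---|---|
| `trondheim` | 0–5; 5 = bilateral pons, 4 = bilateral mesencephalon/thalami (and, by extension, bilateral medulla), 3 = unilateral thalamus/brainstem, cerebellar peduncles, or any basal-ganglia TAI, 2 = corpus callosum, 1 = hemispheres/cerebellum/PL-IC | |
| `standard` | 0–3 (Gentry/Adams); 3 = brainstem incl. peduncles, 2 = corpus callosum, 1 = hemispheres incl. cerebellum and deep grey | deep grey structures are not tiered by this grading |
| `stockholm` | 1–4; 4 = bilateral pons; no-TAI shares grade 1 with hemispheric TAI | **approximate reconstruction** — intermediate tiers are assumptions |
| `gcs_based` | 0–4; 4 = bilateral brainstem or thalami | **approximate reconstruction** |

Open edges resolved as package defaults (all configurable by editing the
rule files): bilateral medulla maps to grade 4 (bilateral non-pontine
brainstem); cerebellar peduncles reach grade 3 but never grades 4–5
without parenchymal brainstem involvement; PL-IC lesions sit in the
grade-1 tier of the Trondheim grading.

The rule engine is tested against hand-coded per-grade predicates over the
exhaustive feature lattice (3⁷·2³ consistent vectors), and a property test
checks that adding a lesion never lowers any grading's grade.

## Outcome construction

The outcome is the GOSE (1–8) at 6 months, modelled as the inverted score
9 − GOSE so that larger response = worse outcome. Patients assessed at 3
and 12 months receive a weighted 6-month score; the original weighting is
unpublished, so the default is linear interpolation in time,
(2·GOSE₃ + GOSE₁₂)/3, rounded half-up and clipped to [1, 8]. Remaining
missing scores are filled by a single deterministic EM imputation under a
joint multivariate-normal model of (GOSE₆, age, GCS, Marshall score,
Trondheim grade, log1p FLAIR TAI volume) — also a reconstruction, since
the original EM variable set is unpublished. The EM iterates conditional
expectations and mean/covariance updates to a 10⁻⁶ log-likelihood
tolerance (max 500 iterations); the observed-data log-likelihood is
asserted non-decreasing at every step, with a 10⁻⁶-relative slack that
covers round-off from the small covariance ridge needed at singular
boundaries (e.g. a perfectly correlated covariate). Imputed values are
rounded half-up and clipped; observed values always pass through
untouched. Dichotomisations: poor outcome = GOSE ≤ 4; disability =
GOSE ≤ 6.

## Adjusted regression models

Proportional-odds (cumulative logit) regression,
P(Y ≤ j | x) = logistic(θⱼ − xβ), is used for severe and moderate
(GCS 9–12) TBI and for all-severity analyses; binary logistic regression
on disability for GCS-13 and mild TBI. Conventions:

- **Volumes** enter as a (presence, ln volume) column pair, ln 0 being
  undefined; the reported OR is per unit of ln(volume in cm³) among
  lesion-positive patients. This makes the log-volume slope invariant to
  unit rescaling (tested: cm³ → mm³).
- **Marshall CT score** is an ordered categorical collapsed to
  {1, 2, 3–4, 5–6}, dummy-coded against 1 (the original coding is
  unstated; integer scoring is available by passing a numeric column).
- **Pupils**: two dummies (unilateral/bilateral dilatation) vs normal.
- **Covariate presets**: severe = age + GCS + pupils + Marshall;
  moderate 9–12 = age + GCS + Marshall; moderate 13 = age + Marshall;
  mild = age + sex. Adjustment dummies for levels absent from a stratum
  (e.g. bilateral pupil dilatation in moderate TBI) are dropped as empty
  categories; a constant *exposure* instead raises an error, which the
  reporting layer converts into a suppressed (NA) row.
- Reporting: OR = exp(β) with Wald 95% CIs, p < 0.01 flagged significant,
  exposures with fewer than 10 carriers suppressed as NA. Fit metrics:
  McFadden pseudo-R² (against the intercepts-only null, available in
  closed form from category frequencies), AIC = −2ℓ + 2k,
  BIC = −2ℓ + k·ln n. Model-comparison tables refuse to mix models whose
  complete-case observation sets differ.

Fitting is by maximum likelihood (quasi-Newton on the threshold
log-increment parameterisation; thresholds are strictly increasing by
construction). Fits are verified against a generic-optimiser oracle on
tiny instances (≤ 10⁻⁴ in log-likelihood), against binary logistic
regression in the two-category case (≤ 10⁻⁶), and against the closed-form
cumulative-logit thresholds for the intercept-only model. Coefficients
above 30 in absolute value, or non-convergence, raise a separation error.

## Elastic-net penalised ordinal regression

The penalised model minimises the negative **mean** cumulative-logit
log-likelihood plus λ·[α·Σ|βⱼ| + (1−α)/2·Σβⱼ²] over the penalised columns
(the TAI variables); age, GCS, pupils and the Marshall score are never
penalised. Two packaged variable lists mirror the study's models: the
*clinical* model (presence/laterality flags) and the *quantitative* model
(adding number and volume totals).

Solver: monotone FISTA — accelerated proximal gradient with backtracking
line search, soft-thresholding for the ℓ1 part (so exact zeros occur), the
ridge part folded into the smooth gradient, and momentum restarts whenever
the accelerated step would raise the objective, so the objective trace is
non-increasing (asserted). Thresholds are optimised jointly through the
log-increment parameterisation. Termination: parameter step < 10⁻⁷ or
subgradient (KKT) violation < 10⁻⁷. Penalised columns are standardised to
mean 0 / SD 1 with full-sample statistics, reused unchanged in bootstrap
refits; coefficients are reported on the original scale. The solver is
validated against the unpenalised fit at λ=0, against scikit-learn's
dedicated ℓ1 and ℓ2 logistic regressions in the two-category limits, and
by direct KKT checks along the path.

Tuning: (λ, α) by stratified 5-fold cross-validation maximising
out-of-fold log-likelihood over a 50-point log-spaced λ path (from
1.02·λ_max, the smallest penalty zeroing all penalised coefficients, down
to 10⁻³·λ_max) × α ∈ {0.1, 0.25, 0.5, 0.75, 1}; ties break toward the
sparser (larger) λ. Tuning is selected once on the full sample and held
fixed across the 500 case-bootstrap refits that produce the inclusion
percentages (re-tuning per resample is not the default — the original
procedure is unstated, and fixed tuning is standard stability-selection
practice and far cheaper). Resamples with fewer than two observed response
categories are redrawn and counted. Unpenalised variables report 100% by
construction.

## Model comparison

Prognostic value is compared by the AUC for predicting poor outcome
(severe TBI) or disability (moderate TBI), computed by stratified 10-fold
cross-validation: the model is refit per training set and held-out
patients receive the model-implied event probability (ordinal models: the
cumulative probability of the event categories; binary models: the fitted
probability). AUC uses the rank (Mann–Whitney) statistic with average-rank
tie handling, computed on the **pooled** out-of-fold pairs (pooling is
more stable than per-fold averaging at these sample sizes; a per-fold mean
is available via `pooled=False`). The 95% CI is a 2000-resample percentile
bootstrap of the pooled (prediction, label) pairs without refitting
(refit bootstrap would multiply cost ~2000×; the original procedure is
unstated). The analysis requires ≥ 10 events and ≥ 10 non-events and
refuses otherwise — mirroring the situation where such analyses cannot be
performed in mild TBI. Gradings enter the comparison as single
integer-scored covariates (0–5) added to the stratum's baseline
covariates.

Trend across ordered GOSE groups is tested with the Jonckheere–Terpstra
statistic: the sum of pairwise Mann–Whitney counts over ordered group
pairs, with the tie-corrected normal approximation and a 0.5 continuity
correction (the statistic lives on a half-integer lattice); for total
n ≤ 12 the exact permutation null is enumerated instead. The normal
approximation agrees with the exact p to < 0.02 for tie-free samples in
this range; with heavy ties at such tiny n the exact method should be
preferred (and is the default there).

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes; it makes
no attempt to reproduce patient-level real data, scanner effects, or
imaging noise. Four strata with sizes 176 / 74 / 55 / 158 (severe,
moderate GCS 9–12, moderate GCS 13, mild) and stratum-specific covariate
distributions read off the printed cohort table (age log-normal around a
median of ~27–33 years; GCS within the stratum's range; pupil abnormality
rates 21%/5% in severe TBI and near zero elsewhere; collapsed Marshall
distributions; Poisson days-to-MRI with stratum means 9/7/6/2).

**Lesion placement is hierarchical**, not independent per location: a
latent severity *tier* — the patient's eventual maximum Trondheim grade —
is drawn first; the tier's defining lesions are placed (e.g. bilateral
pons for tier 5); shallower involvement is filled in with high conditional
probability (hemispheric 0.9 given any deeper lesion, corpus callosum 0.6
given deep involvement, extra unilateral deep lesions 0.3 each in the
worst tiers); cerebellar TAI is only ever generated alongside hemispheric
TAI (matching the observed co-occurrence). The severe-stratum tier
probabilities (0.05, 0.12, 0.30, 0.33, 0.13, 0.07 for tiers 0–5) were
solved once so the marginal prevalences match the printed columns: any TAI
95%, bilateral pons 7%, bilateral mesencephalon/thalami ≈ 16%, any deep
TAI ≈ 53%, corpus callosum ≈ 61%, hemispheric ≈ 88%. The true
co-occurrence correlations are unpublished; the fill-in probabilities are
stated assumptions.

**Volumes**: each patient with FLAIR (resp. DWI) lesions draws a total
volume from a conditional log-normal whose (μ, σ) are solved in closed
form from the printed *unconditional* (median, p75) pair and the
lesion-positive rate (`lognormal_from_quantiles`); the total is split
across lesions by a Dirichlet draw. Severe FLAIR: median 1.33 cm³, p75
5.36 cm³ at 83% positive. Microhaemorrhage counts on T2\*GRE/SWI are
negative-binomial totals distributed over present lesions.

**Outcome**: inverted GOSE drawn from a proportional-odds model on the
realised features. The default effect sizes are the printed severe-stratum
adjusted odds ratios (bilateral pons OR 10.7, unilateral thalamus 3.09,
bilateral basal ganglia 5.42, corpus callosum 2.45, …) plus plausible
covariate effects (age +0.025/yr, GCS −0.12/unit, pupil dummies, Marshall
dummies — these are not printed anywhere and are package choices). The
seven thresholds (−0.16, 0.86, 2.12, 3.62, 4.74, 6.03, 6.49) were
calibrated once by deterministic search so the marginal GOSE bands
approximate the printed outcome distribution (severe: 9/25/45/16% across
GOSE 1–2/3–4/5–6/7–8; mild: ~89% GOSE 7–8) and are stored in the preset,
not re-fit per run. A configurable fraction of severe patients (0.35)
reports 3- and 12-month scores instead of a direct 6-month score, and a
small MCAR missingness rate (3.5%) routes patients to imputation, so the
outcome-construction path is exercised end-to-end.

**Recovery experiments**: because the printed adjusted ORs come from
*separate single-exposure models*, a generating model carrying all of them
at once would make any single-exposure refit inconsistent with any one
printed value (the lesion features are strongly correlated by
construction). `single_exposure_config` therefore derives a
recovery-experiment variant whose outcome is driven by the adjustment
covariates plus one named exposure at its printed log-OR, with outcome
measurement noise (weighting, missingness) switched off; the fitted model
uses exactly the generating covariates, making the check a clean estimator
-consistency experiment. The packaged experiments recover the bilateral-
pons OR (10.7, severe stratum, prevalence 7%) and the log-FLAIR-volume OR
(1.78, all severities, with its paired presence indicator) as the median
fitted OR over 50 cohorts of n = 3000.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; regenerating with the same seed yields
byte-identical cohort tables, and tuning/bootstrap/CV results are
reproducible given their seeds. The shipped experiments use 50 replicates
of n = 3000 for parameter recovery, 500 bootstrap refits at n = 305 for
stability selection, and 10-fold CV with 2000-resample CIs for AUC — sizes
chosen so the full suite runs comfortably on a single CPU while leaving
Monte-Carlo error well inside the tolerances tested.

## Known limitations

- The Stockholm and GCS-based rule sets are approximations anchored only
  on their published worst grades; comparative claims about those gradings
  require the original tier definitions.
- The generator's co-occurrence strengths, covariate effect sizes, GOSE
  weighting and EM variable set are reconstructions, as flagged above;
  passing tests show the *pipeline* recovers what the generator encodes,
  not that the generator reproduces unpublished patient-level structure.
- Proportionality of odds is assumed, not tested (no such test is part of
  the analysis surface), and no random effects are supported.
- Headline fit statistics from the original patient data (pseudo-R²
  values, Table-style AUCs) depend on that unavailable data; the package
  reproduces the analysis machinery and its in-text worked examples, and
  the comparison tables on synthetic cohorts reproduce the qualitative
  ordering (Trondheim > standard grading in severe TBI; combined
  TAI + contusion FLAIR-volume models best) rather than the printed
  numbers.
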