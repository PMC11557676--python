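# taigrade

Anatomical MRI grading of traumatic axonal injury (TAI) and ordinal
outcome models for traumatic brain injury (TBI) cohorts.

After head trauma, shear-type white-matter lesions (TAI, visible on early
MRI as FLAIR/DWI signal change and T2\*GRE/SWI microhaemorrhage) carry
prognostic information that grows with lesion depth: hemispheric lesions
are mildest, corpus-callosum lesions worse, and deep bilateral lesions —
in the thalami, mesencephalon and especially the pons — the most ominous.
`taigrade` implements the full analysis pipeline around this idea for
clinical researchers working with lesion-annotation tables:

- **Cohort data model** — per-patient clinical covariates (age, sex, GCS,
  pupils, Marshall CT score), TAI annotations at 58 predefined anatomical
  locations with laterality on three MRI sequences, contusions, and GOSE
  outcomes, as validated CSV tables.
- **Rule-based gradings** — the Trondheim TAI-MRI grading (grades 0–5;
  5 = bilateral pontine TAI, 4 = bilateral mesencephalic/thalamic TAI),
  the standard Gentry/Adams grading, and approximate reconstructions of
  the Stockholm and GCS-based gradings, all as editable YAML rule sets
  evaluated by a small predicate engine (final grade = highest satisfied
  rule).
- **Outcome construction** — weighted 6-month GOSE from 3/12-month
  assessments, deterministic EM imputation of missing scores, and the
  poor-outcome (GOSE ≤ 4) / disability (GOSE ≤ 6) dichotomisations.
- **Adjusted models** — proportional-odds ordinal regression on the
  inverted GOSE, P(Y ≤ j | x) = logistic(θⱼ − xβ), and binary logistic
  regression, with the study's covariate conventions (volumes as
  presence + ln-volume pairs, collapsed Marshall categories, per-stratum
  covariate presets), OR/CI/p reporting with n < 10 suppression and the
  p < 0.01 significance rule, and pseudo-R²/AIC/BIC model-fit tables.
- **Elastic-net penalised ordinal regression** — objective
  mean-NLL + λ[α‖β‖₁ + (1−α)/2‖β‖₂²] over the TAI variables (core
  covariates and the Marshall score never penalised), solved by monotone
  FISTA with exact zeros, tuned by stratified 5-fold CV, with
  500-bootstrap inclusion percentages for stability selection.
- **Model comparison** — 10-fold cross-validated AUC with percentile
  bootstrap CIs across grading-based and volumetric models, and the
  Jonckheere–Terpstra trend test (exact permutation null for tiny
  samples).
- **Synthetic cohort generator** — hierarchical lesion placement over the
  packaged ontology plus a proportional-odds outcome model, calibrated to
  the published cohort structure (strata 176/74/55/158; any-TAI prevalence
  95/74/64/6%; severe-stratum FLAIR TAI volume median 1.33 cm³; bilateral
  pontine TAI OR 10.7), so the entire pipeline is testable without patient
  data.

## Worked example

```python
import taigrade as tg

# a synthetic cohort with the packaged calibration
cohort = tg.generate(tg.preset_paper(), seed=42)
frame = tg.build_analysis_frame(cohort)   # covariates + features + outcome

# grade every patient with the Trondheim rule set
grades, summary = tg.grade_cohort(cohort, "trondheim",
                                  outcome=frame["gose6"])
print(summary)
```

```
   grade    n  outcome_mean  outcome_sd
0      0  195      7.256410    1.072572
1      1   51      6.549020    1.418643
2      2   85      5.835294    1.541853
3      3   89      5.011236    1.812171
4      4   30      4.533333    1.814374
5      5   13      3.769231    2.314946
```

Mean 6-month GOSE falls monotonically with grade: patients without TAI
average good recovery (7.3), while bilateral pontine TAI (grade 5)
averages 3.8 — severe disability. An adjusted single-exposure model
quantifies the same effect:

```python
spec = tg.ModelSpec("pons", stratum="severe",
                    exposures=[("tai_pons_bil", "identity")])
res = tg.fit_model(frame, spec)
print(res.table.loc["tai_pons_bil", ["or", "ci_low", "ci_high", "p"]])
```

```
or         5.289479
ci_low     1.539875
ci_high    18.16939
p          0.008153
```

— an adjusted odds ratio of ~5.3 (95% CI 1.5–18.2) for worse outcome
given bilateral pontine TAI in this simulated severe-TBI stratum, flagged
significant at the p < 0.01 rule (a single cohort of n = 176 severe
patients estimates this effect with wide uncertainty; the recovery
experiment below shows the estimator centred on the generating value at
scale).

The same pipeline is scriptable from the shell:

```sh
taigrade simulate --seed 42 --out cohort/
taigrade validate --cohort cohort/
taigrade grade --cohort cohort/ --ruleset trondheim --out grades.csv
taigrade fit --cohort cohort/ --stratum severe --out table2.tsv
taigrade elasticnet --cohort cohort/ --model clinical --bootstrap 500 --seed 7 --out stability.json
taigrade compare --cohort cohort/ --stratum severe --folds 10 --seed 11 --out table4.tsv
```

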