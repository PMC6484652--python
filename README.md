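# raforecast

Forecasting next-visit rheumatoid-arthritis (RA) disease activity from
longitudinal electronic health record (EHR) data.

RA care is steered by the Clinical Disease Activity Index (CDAI, range
0–72), binned into remission (≤2.8), low (≤10), moderate (≤22) and high
(>22) activity, and aggregated to a binary state: *controlled* (CDAI ≤ 10)
vs *uncontrolled*. Knowing at today's visit whether a patient will be
uncontrolled at their *next* visit could inform how aggressively to treat.
This package implements that forecasting problem end to end, for
methodologists and clinical-ML practitioners:

* **Synthetic EHR generator** — relational event tables (demographics,
  diagnoses, CDAI scores, ESR/CRP labs, medication prescriptions) driven by
  a latent AR(1) disease severity per patient, with closed-form calibration
  of the controlled fraction and the visit-to-visit outcome switch rate, and
  persisted ground truth. Because the generative model is linear-Gaussian,
  the Bayes-optimal forecast is computable by Kalman filtering and serves as
  a performance ceiling.
* **Cohort construction** — RA inclusion criteria (two ICD-9 714.x codes ≥30
  days apart, ≥1 DMARD, ≥2 CDAI scores, ≥1 inflammation lab), index-visit
  selection and outcome labeling.
* **Fixed-interval featurization** — four 120-day windows counting back from
  the index date; per window the most recent CDAI/ESR/CRP value (missing →
  zero sentinel) and first-occurrence 0/1 indicators for 29 DMARDs and 8
  corticosteroids; five static variables (age, sex, race, RF, anti-CCP).
  The default schema has exactly 165 variables, and the index visit's CDAI
  (the label) can never leak into the features.
* **Models** — a recurrent forecaster (shared per-window dense transform →
  stacked gated recurrent units → sigmoid), a fully dense surrogate, and two
  bespoke baselines: the *outcome posterior* classifier (predicts the
  training outcome frequencies) and the *change posterior* classifier
  (carries each patient's prior outcome forward, flipped at the cohort
  switch rate). The neural networks are implemented in numpy
  (backpropagation-through-time + Adam) and are bit-reproducible given a
  seed. All models are scikit-learn-style estimators.
* **Evaluation** — AUROC (Mann–Whitney) with DeLong confidence intervals,
  grouped permutation importance in percentage points of AUROC, the
  confident-and-wrong rate, per-category subgroup accuracy, learning curves,
  and a t-SNE plot of the learned patient representations.
* **Transfer experiment** — train at a large "university hospital"-like
  site, then compare: a model trained natively on a small second site, the
  large-site model applied directly, and the large-site model fine-tuned on
  the small site's training data.

## Worked example

```python
import raforecast as rf
from raforecast.featurize import matrix_arrays, split
from raforecast.evaluate import auroc, delong_ci
from raforecast.models import (fit_outcome_posterior, predict_outcome_posterior)
from raforecast.synthetic import bayes_optimal_scores

# 2000-patient university-hospital-like cohort (median visit gap 100 d,
# 60% controlled outcomes, 25% visit-to-visit switch rate)
tables, truth = rf.generate(rf.uh_profile(n_patients=2000, seed=7))
members = rf.build_cohort(tables)                    # 1800 qualifying patients
df, schema = rf.build_matrix(members, tables)        # 1800 x 165 features
train, val, test = split(members, rf.SplitSpec(seed=11))

(Xtr, ytr), (Xva, yva), (Xte, yte) = (
    matrix_arrays(df[df.patient_id.isin({m.patient_id for m in part})], schema)
    for part in (train, val, test))

model = rf.RecurrentForecaster(schema=schema, max_epochs=60, patience=10, seed=0)
model.fit(Xtr, ytr, validation_data=(Xva, yva))

r = delong_ci(model.predict_proba(Xte)[:, 1], yte)
print(f"recurrent test AUROC {r.auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f})")

sc = bayes_optimal_scores(truth)                     # generator's Kalman ceiling
print(f"Bayes-optimal AUROC {auroc(sc['score'], sc['label']):.3f}")

om = fit_outcome_posterior(ytr, seed=3)
print(f"outcome posterior AUROC {auroc(predict_outcome_posterior(om, len(yte)), yte):.3f}")
```

Output:

```
recurrent test AUROC 0.817 (95% CI 0.772-0.863)
Bayes-optimal AUROC 0.865
outcome posterior AUROC 0.479
```

The recurrent model recovers most of the information ceiling the generator
admits (0.82 of a possible 0.87), while the outcome-posterior baseline —
which ignores the patient entirely — sits at chance. Permutation importance
attributes most of the model's skill to the CDAI history (combined
importance ≈ 19 AUROC percentage points on this cohort), with small but
significant contributions from ESR and CRP.

A full two-hospital experiment, including the dense surrogate, the change
posterior baseline, the transfer arms and a reproducibility manifest, runs
from one config:

```bash
raforecast run --config examples/experiment.yaml --seed 5
```

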