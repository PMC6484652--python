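# Methods

## The forecasting problem

Each patient in an RA clinic accumulates an irregular sequence of visits
with CDAI scores, inflammation labs (ESR, CRP), medication prescriptions
and static demographics/serologies. The task is binary forecasting: given
everything observed *before* a patient's most recent CDAI-scored visit (the
index visit), predict whether that visit's disease state is uncontrolled
(CDAI > 10). One sample per patient; the penultimate CDAI visit supplies
the "prior outcome" used by the change-posterior baseline.

## Synthetic cohort model

Real rheumatology EHR extracts are private, so the package ships a
generator whose statistical structure matches what the analysis assumes,
with full ground truth persisted. Everything in the generator is the
package's own construction, chosen to reproduce the published marginal
targets; it is not a model fitted to any real data.

**Latent severity.** Patient *i*'s severity follows a stationary AR(1)
across visits: `s_t = μ + φ(s_{t-1} − μ) + ε_t`, `ε_t ~ N(0, σ²)`, with
stationary SD `τ = σ/√(1−φ²)`. Defaults: μ = 0, φ = 0.95, σ chosen so
τ = 1. The AR step is per *visit*, not per day, so the two hospitals share
outcome dynamics while differing in visit cadence — which is exactly the
regime the cross-hospital transfer experiment needs.

**CDAI.** `cdai = clip(g·s + b + e, 0, 72)` with `e ~ N(0, σ_c²)`, rounded
to 0.1. Two calibration targets determine the free constants:

* the *switch rate* (fraction of consecutive visit pairs whose binary
  outcome differs; target 0.25). For a stationary Gaussian pair with common
  threshold at the controlled quantile `z = Φ⁻¹(0.60)` and correlation ρ,
  the switch probability is `4·T(z, √((1−ρ)/(1+ρ)))` (Owen's T). Solving
  for ρ and using ρ = φ·λ, where λ is the signal share of the CDAI
  variance, fixes `σ_c` given the total CDAI spread (SD 8 points). A
  profile whose `φ` is below the required ρ cannot realize its switch
  target and is rejected with a validation error.
* the *controlled fraction* (target 0.60) fixes the intercept `b`, solved
  numerically on the realized index-visit severities so that the expected
  fraction of controlled forecast labels equals the target even under
  treatment-induced drift and finite-sample severity draws.

Clipping at 0 concentrates ~15% of scores at exact remission and does not
affect either binary target (both thresholds sit at CDAI 10).

**Labs.** ESR = 28·exp(0.45·u), CRP = 5·exp(0.80·u), where `u` is the
standardized severity plus N(0, 0.8) noise drawn independently per lab —
positive, right-skewed, monotone in severity (Spearman ≈ 0.75 against
severity), missing completely at random at the profile's per-lab rate
(default 30%, 40% at the sparse site).

**Medications.** 29 DMARD codes (15 conventional synthetic, 13 biologic,
1 tofacitinib) and 8 corticosteroids, placeholder-coded except
"prednisone". Per class, a patient is an ever-user with the profile's
propensity; the start visit is drawn with weight ∝ exp(0.7·standardized
severity), so sicker patients start sooner; refills re-emit the code later
with probability 0.4. A biologic/tofacitinib start lowers severity by the
`treatment_effect` (default 0.15 τ-units) from the *following* visit — a
lagged, treatment-mediated dependence that a recurrent model can exploit
but a memoryless one cannot represent as cleanly. Qualifying patients are
guaranteed at least one DMARD.

**Visit schedule.** Visit count = 2 + Poisson(median − 2); gaps are
log-normal with the profile's median (100 d vs 180 d) and log-SD 0.45;
index dates fall within 90 days of a fixed extraction date.

**Cohort-filter probes.** A configurable fraction (default 10%) of
patients is deliberately made non-qualifying by one randomly chosen
deficiency (single diagnosis code, codes <30 days apart, no DMARD, <2 CDAI
scores, or no labs), so the inclusion filter is exercised against every
criterion; ground truth records which patients were sabotaged and how.

**Bayes-optimal ceiling.** Because the model is linear-Gaussian up to the
CDAI clip and the monotone lab transforms, the true one-step-ahead
`P(CDAI > 10)` is computable by Kalman-filtering each patient's observed
pre-index history (inverting the lab transforms, correcting for known
biologic activity). Clipped CDAI values are treated as exact observations;
this approximation can only *lower* the measured ceiling. On the default
2000-patient profile the ceiling is ≈ 0.87 AUROC.

**What the generator does not emulate.** No informative missingness, no
comorbidities, no medication stop/dose/adherence structure, no provider
effects, no measurement drift between EHR systems. Tests passing on this
generator demonstrate that the pipeline recovers a known signal under the
published marginal structure — not that the model would achieve any
particular performance on real patients.

## Featurization

Four consecutive 120-day windows count backward from the index date
(window 1 oldest, window 4 most recent), a 480-day lookback. Four full
windows keep the tensor rectangular; a 365-day cap is available as config.
Within a window only the most recent value of each continuous variable
survives; empty cells take the zero sentinel. Zero is a clinically
attainable CDAI value, which is a documented imperfection of the
convention; the sentinel is configurable. Each medication contributes
indicators only in its first-occurrence window (stop dates are unreliable
in EHRs, so persistence is unknowable; a carry-forward option exists,
default off). Index-day events are excluded by default — the forecast must
be computable before the visit happens — and the index CDAI itself is
excluded unconditionally. Race is a single integer code rather than
one-hot so the static block is exactly five variables and the flattened
vector exactly 165.

Splits are stratified on the binary outcome with rounded 60/20/20
fractions (largest-remainder allocation across strata), which yields a
116-patient test set from a 578-patient cohort.

## Models

**Recurrent forecaster.** Per window: the 40 time-varying variables plus
the 5 statics (broadcast onto every window) pass through one shared dense
ReLU transform (32 units); the window sequence then feeds stacked GRUs
(32, 16) and a sigmoid head. Training: binary cross-entropy with equal
class weights, Adam at 1e-3, batch 32, inverted dropout 0.5, L2 1e-4,
shuffling each epoch, early stopping on validation AUROC (patience 20,
best weights restored). Defaults are deliberately small and heavily
regularized for cohorts of a few hundred to a few thousand patients; a
random-search hook over a declared space is provided for tuning. The
implementation is plain numpy with manual backpropagation-through-time,
verified against central-difference gradients in the test suite, and is
deterministic given the seed.

**Dense surrogate.** The same trainer on the flattened 165-vector with
ReLU hidden layers (64, 32) — the "logistic-regression-like" comparator.
On the default strong-signal cohort it trails the recurrent model by a few
AUROC points, consistent with part of the signal living in temporal
structure.

**Posterior baselines.** The outcome-posterior classifier predicts
controlled with the training prevalence, ignoring the patient; its
predictions are independent of the truth, so its AUROC converges to 0.5.
The change-posterior classifier returns each patient's prior outcome,
flipped independently at the training switch rate. Scores are the sampled
binary predictions (an analytic-probability variant exists and is
documented as a different estimator). For a two-state chain its AUROC has
a closed form from the transition matrix, used as the test oracle.

**Fine-tuning.** Transfer fine-tuning runs two phases at one-tenth the
learning rate: head-only, then full network. Zero epochs is exactly the
identity; the source model is never modified.

## Evaluation statistics

* **AUROC** is the Mann–Whitney statistic computed from ranks, exactly
  equal to pair counting with half-credit ties.
* **DeLong intervals** use the placement-value variance
  `var(V10)/n₁ + var(V01)/n₀` and a normal quantile, truncated to [0, 1].
  Degenerate inputs (fewer than two of either class) raise rather than
  return a silent value. Empirical coverage under a two-Gaussian score
  model is ≈ 95% (checked over 500 replicates).
* **Permutation importance** is reported in percentage points:
  `PIS = 100·(AUROC − mean permuted AUROC)` over (default) 100
  permutations, with a 2.5/97.5 percentile interval; a group is
  significant when that interval excludes the baseline AUROC. "Combined"
  permutes all of a group's windows jointly — summing per-window scores
  would double-count correlated windows. "Time" importance permutes the
  window *order* within each sample, the only order-destroying transform
  that preserves marginal content. Importance is measured on the test set
  by default (configurable).
* **Confident-and-wrong** uses the 0.2/0.8 probability band for confidence
  and 0.5 for correctness, and can report the index CDAI values of the
  failures (in practice they cluster near the CDAI 10 boundary).
* **Learning curves** subsample the training pool without replacement at
  fixed hyperparameters; the full-pool size reproduces a direct training
  run exactly.
* **Confusion plot**: t-SNE (scikit-learn, PCA init, fixed seed) of the
  final pre-output representations, colored by true outcome.

## Numerical and design choices

* Single global seed fanned out to stages via SHA-256 named substreams
  (`stage_seed`), keeping all child seeds below 2³¹ and collision-free.
* Same-date duplicate CDAI records: last by table order wins, with a
  warning — the data give no principled tie-break, determinism matters.
* The "minimum four months of care" criterion is treated as a consequence
  of the other inclusion rules (an optional explicit span filter exists,
  default off).
* The remission/low boundary is implemented as ≤2.8 vs >2.8; the printed
  "2.9–10" is the integer-rounded rendering of the open interval.
* Eligibility counting uses all records including the index visit's; only
  featurization excludes index-day events.
* Default experiment sizes (2000-patient source, 400-patient target with a
  0.35/0.15/0.50 split giving a ~125-patient native training set, 60-epoch
  training for the heavy suites, 30-repeat importance) were chosen to make
  a full run complete in about a minute on one CPU while leaving the
  measured effects several standard errors wide.

## Known limitations

The generator's calibration tolerances (±0.03 on the outcome fractions)
are Monte-Carlo, not exact; very small cohorts will wander further. The
Kalman ceiling is slightly conservative under CDAI clipping. The neural
nets are CPU-only by design and not optimized for cohorts beyond ~10⁵
samples. Binary outcome only: four-category CDAI prediction and
probability calibration are out of scope.
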