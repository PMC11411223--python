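# Methods

## Problem and pipeline

`sepsistraj` implements a prognostic-enrichment pipeline for sepsis
clinical trials. Patients with sepsis who need vasopressors are a
heterogeneous population; a trial of, say, a vasopressor-sparing therapy is
most informative if it enrolls patients likely to remain vasopressor-
dependent ("persistent ill") rather than those about to recover or die
regardless of treatment. The pipeline stratifies patients at enrollment
(24 h after sepsis onset) into three 48-h disease-progression trajectories
and quantifies the uncertainty of each prediction so that ambiguous cases
can be deferred to a human reviewer instead of silently misclassified.

Stages: synthetic ICU event generation → Sepsis-3 onset detection →
inclusion/exclusion → trajectory labeling → 24-h-window feature building →
three-class modelling → Mondrian conformal prediction → evaluation and
reporting.

## Onset detection (Sepsis-3)

* **Suspicion of infection** `t_susp`: earliest `min(a, c)` over
  antibiotic/culture pairs with the culture within 24 h after the
  antibiotic, or the antibiotic within 72 h after the culture. Closed
  inequalities at both window ends.
* **Organ dysfunction** `t_SOFA`: earliest record whose SOFA total score
  exceeds the minimum score over the preceding 24 h (half-open lookback
  `[t−24, t)`) by ≥2 points. The baseline for the 2-point rise is not
  uniquely defined in the literature; the rolling minimum is used here (the
  most sensitive choice); "first value in the window" is a noted
  alternative.
* **Onset** `t_sepsis = min(t_susp, t_SOFA)` provided
  `t_susp − 24 h ≤ t_SOFA ≤ t_susp + 12 h`; otherwise the patient is not
  septic.

Inclusion requires onset within 24 h of ICU admission, age ≥18,
vasopressor initiation within 24 h of onset (any positive-rate infusion
interval starting in `[t_sepsis, t_sepsis + 24 h]`), survival and ICU stay
of ≥24 h, and first ICU admission only. Criteria are evaluated in that
fixed order so each excluded patient carries exactly one machine-readable
reason (`no_onset`, `late_onset`, `age`, `no_vasopressor_24h`,
`early_death`, `short_icu_stay`, `not_first_icu_stay`).

## Trajectory labels

Enrollment is `t_sepsis + 24 h`; the outcome window is the following 48 h.
Raw infusion rows are merged into maximal episodes (gaps ≤1 h joined,
configurable; zero-rate rows ignored), then:

* **0 — rapid death**: death within the window. Death dominates any
  weaning (the categories are not otherwise mutually exclusive).
* **2 — recovery**: every episode overlapping the window ends inside it,
  and every in-window liberation is maintained for ≥24 h (no episode starts
  within 24 h after it). The maintenance check is anchored at the
  liberation time and may extend past hour 48. A patient with no
  vasopressor activity after enrollment is liberated at enrollment.
* **1 — persistent ill**: everything else — support still running at hour
  48 (`ongoing_support`) or a liberation followed by a restart within 24 h
  (`weaned_not_held`), including restarts that run past the window.

A restart within 24 h of *any* in-window liberation fails the maintenance
requirement even if a later wean holds; this is the conservative reading
for an enrichment target that is supposed to capture sustained vasopressor
need.

## Features

Time-varying variables are summarised over the half-open window
`[t_sepsis, t_enroll)` by maximum, minimum, median and coefficient of
variation (sample SD / mean). The CV is masked (missing, never zero) for
fewer than two measurements or a zero-mean window; empty windows mask all
four summaries. Raw observations outside per-variable physiologic bounds
(closed intervals, `data/registry.yaml`) are discarded first.

The combined vasopressor dose enters as the norepinephrine equivalence

    NEE (μg/kg/min) = norepinephrine + epinephrine + phenylephrine/10
                      + dopamine/100 + 2.5 × vasopressin (U/min)

sampled hourly across the window; absolute μg/min rates are divided by
body weight. The factors are a standard equivalence table and are
configurable in the registry.

The default registry ships 35 time-varying variables (including derived
NEE) × 4 summaries, a urine-output window total (urine output is
clinically a cumulative volume), and 4 static variables (age, sex, weight,
onset-to-admission interval) — 145 columns. Mean imputation is fitted on
training rows only and is part of the fitted model for architectures that
cannot handle missing values (random forest, logistic regression; gradient
boosting consumes NaNs natively).

## Models

Three architectures (LightGBM gradient boosting, random forest, logistic
regression with standardisation) × three setups:

* `two_way`: persistent ill vs rest. The 3-class triple is derived by
  splitting `1 − p₁` over labels 0/2 proportionally to training
  prevalence; it is a labelled convenience and is excluded from conformal
  use.
* `nested`: stage A rapid death vs rest; stage B (non-rapid-death rows)
  persistent ill vs recovery; chain rule
  `p = (p_A, (1−p_A)p_B, (1−p_A)(1−p_B))`.
* `multiclass`: one native 3-class learner.

Point predictions: argmax for multiclass (ties to the lower label — rapid
death first, the conservative choice for a safety-relevant class); for the
binary stages, thresholds maximising F₀.₅ = 5·TP/(5·TP + FN + 4·FP)
over the unique-score grid, ties to the higher threshold. The integer form
of F₀.₅ is used so mathematically tied thresholds compare exactly.

Hyperparameter search (optional, off by default) maximises
calibration-set persistent-ill AUROC with a seeded Gaussian-process
expected-improvement loop; plain random search is available as the
fallback.

## Mondrian conformal prediction

Nonconformity is the inverse probability `1 − p_class`. Each calibration
patient contributes one score to its true class's list; for a test patient
and candidate class `c`,

    p_c = (#{calibration scores of class c ≥ test score} + 1) / (n_c + 1),

and the region at significance vector ε is `{c : p_c > ε_c}`. Working per
class gives the class-conditional coverage guarantee
`P(error in class c) ≤ ε_c`, which matters with a 4% rapid-death class.
Ties count as "≥"; unsmoothed p-values (conservative) are the default, a
smoothed variant (seeded uniform tie-break) is exactly uniform under
exchangeability and exists for calibration diagnostics. The development
set is split 80% training / 20% calibration, stratified by class and
seeded. The mixed-confidence default is 85% for recovery and 75% for rapid
death and persistent ill (ε = 0.15/0.25/0.25): the majority class supports
a higher confidence without producing uninformative regions.

Region accounting per true class: `empty` (no labels), `error` (non-empty,
truth excluded), `single` (exactly the truth), `multiple` (≥2 labels
including the truth); the four categories partition each class, and
`(empty + error)/n_c` is the quantity the validity guarantee bounds.
Efficiency is the fraction of single correct predictions. In the deferral
workflow, `multiple` and `empty` regions are handed to a human reviewer;
only asserted-but-wrong regions count as committed errors.

## Synthetic cohort generator

The generator emits the raw tables a hospital data warehouse would
provide (patients, observations, infusions, antibiotics, cultures, SOFA
series) with one of the three trajectory classes planted per patient at
configurable prevalences, default 4.0% / 32.1% / 63.9%. Antibiotic,
culture and SOFA events are placed so the Sepsis-3 rules recover the
planted onset *exactly*; vasopressor episodes are built so the labeling
rules recover the planted class exactly when no eligibility violations are
planted — this is the round-trip oracle the tests lean on.

Class-conditional dynamics are piecewise-linear mean trajectories plus
Gaussian noise, parameterised in `SimConfig.effect_params`:

| parameter | rapid death | persistent ill | recovery |
|---|---|---|---|
| NEE at onset (μg/kg/min) | 0.50, slope +0.006/h | 0.42, flat | 0.26, weaning to ~0.04 at liberation |
| heart rate (bpm) | 106 | 94 | 88 |
| systolic BP (mm Hg) | 90 | 102 | 110 |
| lactate (mmol/L) | 3.6 | 2.8 | 1.9 |
| urine output (mL/h) | 15 | 30 | 55 |

plus weaker class effects on respiratory rate, SpO₂, temperature and GCS,
and 21 class-independent laboratory variables. Between-patient
heterogeneity (NEE severity offset SD 0.09 μg/kg/min; per-patient vital
offsets) keeps the classes realistically overlapping: the multiclass GBM
lands at one-vs-rest AUROCs around 0.95–0.99 on held-out data rather than
at a clean 1.0, and argmax point predictions err on roughly a tenth of
patients. These effect sizes were chosen once to emulate the qualitative
trends of real sepsis trajectory cohorts (sustained high NEE with
tachycardia and hypotension before rapid death; weaning NEE in recovery).

Other defaults, chosen once: vitals charted hourly, labs 6-hourly, 5%
missingness per scheduled observation, 168-h horizon, 10% of patients
generated with exactly one planted eligibility violation (one of: age
<18, death <24 h post-onset, ICU stay <24 h, vasopressor start >24 h
post-onset) so each exclusion reason is individually testable.

What the generator does **not** emulate: organ-level SOFA components
(only the total score is emitted — onset detection needs nothing more),
pharmacokinetics and dose titration, documentation artefacts beyond
fragmented infusion rows and zero-rate records, inter-variable
correlation structure beyond the class labels, admission-diagnosis-based
sepsis identification (the external-cohort pathway, which has no
computable published rule), and calendar/seasonal structure. Passing
tests therefore demonstrate the correctness of the pipeline's logic and
its statistical guarantees under exchangeable data — not model transfer
to real EHR distributions.

Because the planted classes are better separated than real cohorts, the
fitted models are more confident than their real-data counterparts: at the
mixed significance vector, prediction uncertainty surfaces mostly as empty
regions (deferrals of atypical patients) rather than multiple-label
regions.

## Numerical choices

* Time is real-valued hours since a fixed epoch; all generated event times
  are quantized to whole milliseconds in the exact float form the
  ISO-8601 (ms) file round trip reproduces, so write→read is bitwise
  lossless and oracle tests can demand exact equality.
* Window inequalities are closed at both ends throughout the onset rules.
* An infusion record is active on `[start, end)`.
* CV uses the sample SD (n−1). Outlier bounds are closed intervals.
* Brier scores are reported per class in the binary form (the summed
  multiclass form is also emitted); calibration deciles are
  probability-quantile bins with Wilson 95% CIs.
* Cross-validation defaults to 10 folds × 50 repeats; imputation, F₀.₅
  cutoffs and top-k feature selection are refitted inside each training
  fold. Tests and examples run reduced plans (e.g. 3×1) by configuration,
  and the statistical test fixtures use studies of 3,000 training / 800
  calibration / 3,000–5,000 test patients.

## Validating the coverage guarantee

Two subtleties in testing conformal calibration are easy to get wrong and
are handled explicitly:

* The Mondrian bound `P(p_true ≤ ε) ≤ ε` is a statement about the joint
  draw of calibration set and test point. The observed per-class error of
  a single study fluctuates with SD roughly double the test-set binomial
  SD, because an 800-patient calibration set (32 rapid-death scores)
  contributes comparable sampling noise. The validity check therefore
  averages the observed error over three disjoint replicate studies before
  applying the 3-binomial-SD tolerance.
* Smoothed p-values are uniform *marginally*; conditional on one
  calibration draw they deviate from uniform by ~m^(−1/2). A
  Kolmogorov–Smirnov test at 5,000 test points resolves ~0.023, so the
  uniformity check uses a calibration set of ~12,400 patients, at which
  the conditional law is within KS resolution of its uniform marginal.

## Known limitations

* The two-way setup's 3-class triple is a prevalence-based convenience;
  AUROCs for classes 0/2 under that setup are not meaningful.
* Exact per-patient attributions are available for the gradient-boosting
  and logistic multiclass models; random forests fall back to permutation
  importance.
* The nested setup's chain-rule probability combination is one reasonable
  construction; stage-B probabilities are extrapolated to rapid-death-like
  patients it never saw.
* The conformal guarantee is class-conditional coverage, not region
  usefulness: at aggressive significance levels the predictor trades
  errors for empty regions, and the efficiency/deferral curves should be
  inspected before choosing ε.
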