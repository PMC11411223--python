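# sepsistraj

Trajectory-based patient stratification for sepsis clinical trials, with
Mondrian conformal prediction for deferring uncertain cases to human
review.

## The problem

Sepsis trials enroll a heterogeneous population, which dilutes treatment
effects. A prognostic-enrichment strategy instead targets the patients a
given therapy can plausibly help — for vasopressor-directed therapies,
those likely to *remain* vasopressor-dependent. `sepsistraj` stratifies
patients with sepsis requiring vasopressors, at enrollment 24 h after
sepsis onset, into three 48-h disease-progression trajectories:

* **0 — rapid death**: died within 48 h of enrollment;
* **1 — persistent ill**: ongoing vasopressor need through the window;
* **2 — recovery**: liberated from vasopressors within 48 h and kept off
  them for ≥24 h.

Sepsis onset follows the Sepsis-3 construction: `t_sepsis =
min(t_suspicion, t_SOFA)` where `t_suspicion` is the earlier of a
qualifying antibiotic/culture pair (culture ≤24 h after antibiotic, or
antibiotic ≤72 h after culture) and `t_SOFA` is the earliest ≥2-point SOFA
rise within 24 h, accepted when
`t_suspicion − 24 h ≤ t_SOFA ≤ t_suspicion + 12 h`.

Time-varying predictors are summarised over the 24 h between
identification and enrollment (max / min / median / coefficient of
variation), with vasopressor burden expressed as norepinephrine
equivalence, NEE = norepi + epi + phenylephrine/10 + dopamine/100 +
2.5·vasopressin (μg/kg/min). Three-class models (gradient boosting, random
forest, logistic regression; two-way, nested, and multiclass setups)
produce probability triples `(p₀, p₁, p₂)`.

On top of the classifier sits a **Mondrian (class-conditional) conformal
predictor**: calibration patients contribute nonconformity scores
`1 − p_true` to their true class, and a test patient's region at
significance ε is

    Γ(x) = { c : (#{s ∈ S_c : s ≥ 1 − p_c(x)} + 1) / (n_c + 1) > ε_c }.

Working per class guarantees `P(true class ∉ Γ) ≤ ε_c` *within each
class*, despite the 4% / 32% / 64% imbalance. Regions with several labels
(or none) are deferred to a human reviewer; only asserted-but-wrong
regions are committed errors, so deferral reduces the error rate relative
to always predicting the argmax. The default mixed-confidence vector uses
85% confidence for recovery and 75% for rapid death and persistent ill.

Because the real cohorts behind this design are credentialed-access
clinical databases, the package ships a seeded synthetic ICU event-stream
generator that plants the three trajectories with recoverable ground
truth; every pipeline stage is tested against it (see
`docs/methods.md`).

## Worked example

```python
from sepsistraj import (SimConfig, generate, build_cohort, label_cohort,
                        build_matrix, split_development_set,
                        TrajectoryClassifier, MondrianConformal,
                        DEFAULT_MIXED_EPS)

bundles, truth = generate(SimConfig(n_patients=2000, seed=0))
cohort = build_cohort(bundles)
labeled, summary = label_cohort(cohort, bundles)
print(summary.to_string(index=False))
```

```
 trajectory           name  count  proportion
          0    rapid_death     77    0.042897
          1 persistent_ill    566    0.315320
          2       recovery   1152    0.641783
```

Of 2,000 simulated admissions, 1,795 meet the inclusion criteria (the
rest carry one machine-readable exclusion reason each), and the labeled
prevalences track the configured 4.0/32.1/63.9% priors.

```python
matrix = build_matrix(labeled, bundles)          # 1795 patients × 145 features
y = (labeled.set_index("patient_id")
     .loc[matrix.patient_ids, "trajectory"].astype(int).to_numpy())

tr, cal = split_development_set(y, train_frac=0.8, seed=0)
res = TrajectoryClassifier(matrix.X.iloc[tr], y[tr],
                           architecture="gbm", setup="multiclass",
                           seed=0).fit()
print(res.summary())
```

```
Trajectory classifier results
==============================================
architecture:          gbm   setup: multiclass
n = 1436  (rapid death 62, persistent ill 453, recovery 921)
features: 145
imputation: none
```

```python
conf = MondrianConformal(res).calibrate(matrix.X.iloc[cal], y[cal])
print(conf.predict(matrix.X.iloc[cal[:5]], eps=DEFAULT_MIXED_EPS).round(3))
```

```
               p0     p1     p2 region category
patient_id
P00002      0.062  0.544  0.013    {1}   single
P00012      0.062  0.061  0.263    {2}   single
P00016      0.062  0.018  0.737    {2}   single
P00017      0.062  0.447  0.022    {1}   single
P00023      0.062  0.018  0.578    {2}   single
```

Each row shows the conformal p-value per candidate class and the resulting
prediction region: `p1 = 0.544` for P00002 means more than half of the
persistent-ill calibration patients looked less typical than this patient
does under that label, so persistent ill stays in the region, while rapid
death (`p0 = 0.062 ≤ 0.25`) and recovery (`p2 = 0.013 ≤ 0.15`) are
excluded — a confident single prediction. A `multiple` or `empty` category
marks a patient the model cannot commit on; in a screening workflow those
are routed to clinician review.

The same stages are available as a CLI:

```sh
sepsistraj simulate --out data/ --seed 0 --n 2000
sepsistraj build-cohort --in data/ --out cohort.csv
sepsistraj label --cohort cohort.csv --in data/ --out labeled.csv
sepsistraj featurize --cohort labeled.csv --in data/ --out features.csv
sepsistraj train --features features.csv --labels labeled.csv \
                 --arch gbm --setup multiclass --out model.pkl
sepsistraj conformal-eval --model model.pkl --features features.csv \
                 --labels labeled.csv --eps "0:0.25,1:0.25,2:0.15" --out cp/
sepsistraj report --out report/          # full pipeline + manifest
```

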