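# osascreen

Bayesian screening for obstructive sleep apnea (OSA), with the complete
validation machinery a clinical prediction rule needs.

Diagnosing OSA requires polysomnography (PSG) — an expensive, capacity-limited
sleep study. Screening tools that estimate the pre-test probability of OSA
from bedside information let clinics refer only the patients likely to
benefit. `osascreen` implements such a tool as a **tree-augmented naive Bayes
(TAN) classifier** over six categorical predictors — sex, age band, increased
neck circumference, craniofacial abnormalities, witnessed apneas, and
nocturia — and everything needed to validate it against a PSG-labelled cohort:
ROC/AUC with DeLong confidence intervals, sensitivity-constrained cutoff
selection, and the full diagnostic-accuracy battery (sensitivity, specificity,
predictive values, likelihood ratios, pre/post-test odds, diagnostic odds
ratio, F-score) with 95% CIs.

It is written for biostatisticians and clinical-epidemiology researchers:
scikit-learn estimator conventions, plain-text formats (CSV cohorts, JSON
models and reports), and a small CLI.

## The model

A TAN relaxes naive Bayes by allowing each predictor one extra parent besides
the class, the feature–feature edges forming a tree:

    P(c, x_1..x_k) = P(c) · ∏_i P(x_i | c, x_pa(i))

Structure is learned Chow–Liu style: a maximum-weight spanning tree over the
complete feature graph, weighted by the class-conditional mutual information
I(X_i; X_j | C) estimated from Laplace-smoothed counts; parameters are
smoothed relative frequencies. The screening score is the exact posterior
P(OSA | evidence). Missing predictors are never imputed: they are summed out
of the factorized joint (exact marginalization in log space), so the score is
defined for *any* subset of observed inputs, including none (which returns
the class prior).

The outcome label is the apnea–hypopnea index (AHI) from PSG: OSA is
AHI ≥ 5 events/h, moderate/severe OSA is AHI ≥ 15 events/h. The referral
cutoff on the score is chosen from the ROC curve as the highest-specificity
operating point with sensitivity ≥ 95% (screening must not miss cases);
a subject is screen-positive when the score is strictly greater than the
cutoff.

Because the original study cohort is not publicly available, the package
ships a seeded synthetic-cohort generator (`osascreen.simulate`) whose
defaults reproduce the published cohort statistics: n=216, 82% OSA
prevalence, a 73/143 PSG I / PSG III split with stratum prevalences 66% / 90%,
a 44/32/24% mild/moderate/severe mix, and class-conditional distributions for
every predictor.

## Worked example

```sh
osascreen simulate --n 400 --seed 5 --out cohort.csv
osascreen fit --cohort cohort.csv --out model.json
osascreen validate --cohort cohort.csv --model model.json --out report.json
```

prints:

```
wrote 400 records to cohort.csv
fitted on 400 subjects (0 without AHI skipped)
tree: root=age_band; age_band->cfa, age_band->nocturia, age_band->sex, age_band->witnessed_apneas, nocturia->nc_increased
model written to model.json
cutoff: 0.5294
AHI>=5/h, all: n=400, AUC=88.6%
AHI>=5/h, III: n=269, AUC=90.9%
AHI>=5/h, I: n=131, AUC=88.8%
AHI>=15/h, all: n=400, AUC=60.0%
...
```

The `tree` line is the learned feature tree (every feature also has the class
as a parent). The `cutoff` is the auto-selected referral threshold: the
screening score above which a subject would be referred for PSG, chosen so
that at least 95% of true OSA cases are referred on this cohort. Each `AUC`
line is the discrimination of the score in one stratum at one outcome
threshold; `report.json` carries the full metric battery with CIs per cell.

The same in Python:

```python
import osascreen as osa

records = osa.generate_cohort(seed=5)                 # synthetic cohort, n=216
X = osa.encode_cohort(records)                        # six categorical predictors
y = [r.ahi_events_per_hour >= 5 for r in records]     # PSG label
model = osa.TANClassifier(alpha=1.0).fit(X, y)
scores = model.predict_osa_probability(X)             # P(OSA | evidence)
report = osa.run_validation(records, model=model)
print(report.cells[("all", 5.0)]["auc"])              # e.g. 0.906
```

A published report can also be turned back into exact counts and the full
battery, e.g. for a cohort of 216 with 177 cases, sensitivity 96.6% and
specificity 41.0%:

```sh
osascreen reconstruct --n 216 --n-pos 177 --sensitivity 0.966 --specificity 0.410
```

```
table: tp=171 fn=6 fp=23 tn=16
sensitivity: 96.6
specificity: 41.0
ppv: 88.1
npv: 72.7
accuracy: 86.6
lr_pos: 1.64
lr_neg: 0.08
...
```

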