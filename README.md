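# emlscreen

Ensemble machine-learning screening on serum metabolomic profiles.

Endometrial carcinoma (EC) has no validated population screening test;
serum metabolomics — hundreds of GC-MS peak intensities from a dried blood
spot — is a cheap, non-invasive candidate readout. `emlscreen` implements
the full analysis such a screening study needs, as a tested, reusable
Python library plus CLI, for biostatisticians and metabolomics researchers
who want to train, deploy and evaluate an ensemble screening classifier on
case–control feature tables (real or simulated).

## The model

Ten base classifiers (decision tree, PLS-DA, naive Bayes, random forest,
kNN, a shallow and a deep neural network, RBF SVM, LDA, logistic
regression) are trained on a labeled training cohort after a 75%-presence
feature filter, half-minimum imputation and log + z-score scaling. Each
member *i* receives a weight *wᵢ* equal to its stratified cross-validation
accuracy, measured on one shared seeded fold partition. For a screened
sample, each member votes with a signed model score

&nbsp;&nbsp;&nbsp;&nbsp;*sᵢ = ±(100·wᵢ)·cᵢ*,

where *cᵢ* ∈ [0,1] is the confidence of the class the member predicted and
control votes carry the minus sign. The **EC-EML score** is Σᵢ *sᵢ*
(positive ⇒ the weighted votes favour EC). Class assignment uses the
normalized weighted membership probability Σᵢwᵢpᵢ(EC)/Σᵢwᵢ with a strict
> 50% rule; the score with a cutoff (0, or the Youden-optimal cutoff
maximizing J = sensitivity + specificity − 1) is the continuous
alternative. Evaluation covers the confusion-matrix indices (sensitivity,
specificity, PPV, NPV, LR±, accuracy, with binomial SEs and "ND" for
undefined ratios), ROC/AUC with DeLong variance, and PLS-DA permutation
validation (R²Y, Q²Y, separation-distance null).

Because clinical serum metabolomes are generally not deposited, the package
includes a first-class synthetic cohort generator (log-normal intensities,
configurable class signal, missing-at-random dropout, engineered
low-presence peaks) so the entire pipeline is testable end-to-end. See
`docs/methods.md` for the model, defaults, and what a green test does and
does not establish.

## Worked example

Run the default demo study — a 50-case / 70-control training cohort and an
independent 1430-sample screening cohort at 1.12% prevalence, 293 features
of which 268 survive the presence filter:

```sh
$ eml-screen run-all --seed 1 --out results/demo
AUC 0.9984  sens 0.9375  spec 0.9936350777934936  outputs in results/demo
```

`results/demo/metrics.json` then holds, among others:

```
"cv_accuracies": { "decision_tree": 0.825, ..., "random_forest": 0.992,
                   "svm": 0.992, "logistic_regression": 0.975, "lda": 0.817 }
"plsda_validation": { "r2y": 0.998, "q2y": 0.793, "p_value": 0.001 }
"roc": { "auc": 0.9984, "youden_cutoff": -366.16 }
```

Reading: the ten members' cross-validation accuracies (the ensemble
weights) span 0.82–0.99 on this simulated training cohort; the PLS-DA
permutation test rejects chance separation at the minimum achievable
p = 1/1001; and on the screening cohort the EC-EML score discriminates with
AUC 0.998, catching 15 of the 16 true cases (sensitivity 0.938) with 9
false positives among 1414 controls (specificity 0.994).
`performance_table.csv` lays the same numbers out one row per model plus
ensemble rows for training (CV) and test, and `scores.csv` carries each
sample's per-model scores, EC-EML score and class call. Stage-wise verbs
(`simulate`, `train`, `screen`, `evaluate`) exchange the same CSV/JSON
formats, so real GC-MS feature tables (CSV: `sample_id`, `label`, one
column per metabolite, empty cell = missing) drop in at `train`/`screen`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the default screening study from scratch — simulates both
cohorts, fits the weighted ensemble, scores the screening cohort and
evaluates it — printing a summary and writing the acceptance JSON.
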