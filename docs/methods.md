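# Methods

`emlscreen` implements and evaluates an ensemble machine-learning (EML)
screening classifier for endometrial carcinoma (EC) built on serum GC-MS
metabolomic feature tables, together with a synthetic cohort generator that
makes every stage testable without access to clinical metabolomes.

## The screening model

**Feature retention.** A peak is retained only if it is observed
(non-missing) in at least a fraction `presence_threshold` (default 0.75,
inclusive) of training samples. Features whose observed values are constant
are also dropped; this zero-variance rule is the only computable stand-in
for spectral-quality exclusions, which require raw spectra. The keep-list is
learned on the training cohort and applied unchanged to screening cohorts,
mirroring how a deployed signature stays fixed.

**Imputation and scaling.** Residual missing cells are filled with half the
feature's minimum observed value (`half_min`, the standard metabolomics
convention for left-censored peaks; `feature_median` is available). Features
are then log-transformed and standardized to mean 0, sd 1. Both steps are
fit-on-train / apply-on-test objects: inside cross-validation they are
refitted on each training fold, and at screening time the stored training
parameters are reused verbatim — no leakage in either place.

**The classifier bank.** Ten base models: decision tree (CART, depth ≤ 5),
PLS-DA (5 latent components), Gaussian naive Bayes, random forest (500
trees), k-nearest neighbours (k = 5, Euclidean), a one-hidden-layer neural
network (16 units), an RBF SVM with Platt-scaled probabilities, linear
discriminant analysis, logistic regression, and a deeper multilayer
perceptron (64-32-16) distinguished from the shallow network only by depth.
Hyperparameters are conventional defaults and all overridable. Each model
exposes a two-class membership probability; for models without a native
probability we use the field-standard surrogate (neighbour vote fraction for
kNN, Platt calibration for the SVM, Gaussian posteriors on the latent
discriminant score for PLS-DA). A sample is called EC by a member iff its EC
confidence strictly exceeds 0.5; the tie goes to control, favouring
specificity in a screening setting.

**Weights.** Every member is cross-validated (stratified k-fold, default
k = 10) on one seeded fold partition shared by the whole bank, so the
resulting accuracies are comparable; each member's CV accuracy becomes its
ensemble weight. Members are then refitted on the full training cohort.

**EC-EML score.** For a screened sample, member *i* with weight *wᵢ*
contributes a signed model score

    sᵢ = ± (100·wᵢ) · cᵢ

where *cᵢ* is the confidence of the class the member predicted and the sign
is negative for a control vote. The EC-EML score is Σᵢ sᵢ. The 0–100
accuracy scale is the default because a published Youden cutoff of ≈285 is
only reachable when individual scores span ±100; a fraction scale is
available and classifications are invariant to the choice.

**Class assignment.** The default decision device is the normalized weighted
EC-membership probability p = Σ wᵢ pᵢ(EC) / Σ wᵢ with a strict > 0.5 rule
(p = 0.5, the balanced-votes case, is called control). The EC-EML score with
a cutoff (0, or the Youden-optimal cutoff from the ROC sweep) is the
continuous-marker alternative; with equal weights and symmetric confidences
the two devices agree, which is enumeration-tested.

## Evaluation

**Screening metrics.** Sensitivity, specificity, PPV, NPV, accuracy,
likelihood ratios and prevalence from the confusion matrix, with binomial
standard errors √(p(1−p)/n) on each proportion's own denominator. A metric
with a zero denominator — e.g. LR+ of a perfectly specific test — is
*undefined* and rendered "ND", never coerced to 0 or 1.

**ROC / Youden.** The decision rule is `score > t`; candidate cutoffs are
midpoints between consecutive distinct scores plus outer sentinels, so every
achievable operating point is swept. AUC is the trapezoidal area, which
equals the Mann–Whitney pair-count estimator (ties counted half). The Youden
cutoff maximizes J = sensitivity + specificity − 1; ties break toward higher
specificity.

**DeLong comparison.** Correlated AUCs are compared with the placement-value
(structural-components) estimator: per-case and per-control placements give
the variances and covariance, z = (AUC_a − AUC_b)/√(var_a + var_b − 2cov),
two-sided normal p. No continuity corrections. A degenerate variance of the
difference is reported as undefined z (p = 1 only when the difference is
exactly zero).

**PLS-DA permutation validation.** A two-class PLS regression on the 0/1
label gives R²Y (in-fit explained label variance) and Q²Y (7-fold
cross-validated analogue; fold count configurable). The permutation
statistic — unspecified in the source literature beyond "separation
distance" — is the distance between class centroids in the latent score
space divided by the pooled within-class spread, i.e. a latent-space effect
size. The null is built by refitting on permuted labels;
p = (1 + #{permuted ≥ observed}) / (B + 1).

## The synthetic generator: what it states and what it is not

Cohorts are drawn from per-feature log-normal intensity models (GC-MS peak
areas are positive and right-skewed; no distribution is published, so this
is the package's choice). Defaults state the study world being emulated: a
training cohort of 50 EC / 70 controls, a screening cohort of 16 / 1414
(prevalence 1.12%), 293 features of which 25 are engineered below the
presence rule (so 268 survive), base log-mean 12 and log-sd 1 (peak areas
around 1.6×10⁵), 5% missing-at-random dropout, and a class signal of
effect size 1.2 on 30 informative features — a Bayes-rule separation of
√30·1.2 ≈ 6.6 sd, i.e. an almost perfectly separable signature, matching
the near-ceiling training accuracies the model bank is expected to show.

Engineered low-presence features have exactly ⌈n/2⌉ cells removed, so their
observed presence is ≤ 0.5 and deterministically below the 0.75 rule.
Randomness is drawn from one seed via per-(purpose, column) substreams, so
adding features never perturbs earlier columns and identical configs are
bit-identical. Optional modes: intensity-dependent left-censoring dropout,
and equicorrelated feature blocks for robustness experiments (independence
is the default because no covariance structure is published).

What the generator does **not** emulate: named metabolite identities,
retention-time structure, batch and instrument drift, covariate-metabolome
coupling, or realistic inter-feature correlation. A green test therefore
establishes that the pipeline's statistics behave correctly in a stated
world — not that the published clinical performance is reproducible, which
would require the undeposited serum metabolomes.

The oracle closed form used in calibration tests: with m informative
features shifted by d on a log scale of spread σ, the optimal linear rule
has per-class error Φ(−√m·d/(2σ)). The parameter-recovery check designs
d = 0.8106 with m = 10 (operating point Φ(1.28) = 0.900 sensitivity and
specificity) and requires the fitted ensemble to land within ±0.05 of it on
independent screening cohorts, averaged over 10 seeds.

## Numerical and design choices

- Demographics: pack-years = cigarettes/day × years smoked / 20; NCCN
  smoke-risk classes evaluated most-severe-first, with the very-high rule
  exempted for individuals who quit more than 15 years ago.
- Stage seeds derive deterministically from one global run seed; the run
  manifest (config, seed, output hashes) suffices to reproduce every output
  byte-for-byte.
- Members that fail to train abort the ensemble fit rather than silently
  shrinking it.
- Permutation counts are scaled in tests (B = 49–199) and in the acceptance
  run (B = 200) against the conventional B = 1000 default, purely for
  runtime; p-value resolution changes, the statistic does not.
- Screening-cohort labels flow only into the evaluation stage; scoring never
  reads them.

## Known limitations

- The per-model "classification confidence" is taken as the predicted
  class's probability (the sign rule then orients it); interpreting it as
  the EC probability always would flip no classifications but would change
  score magnitudes for control votes.
- Whether intensities should be normalized (e.g. to total ion current)
  before modelling is unknown; exposed as an option, default off.
- The ensemble output probability is not calibrated; it is a weighted vote,
  not a posterior.
- CV flavour (k-fold vs leave-one-out vs repeated) in the original protocol
  is unstated; k = 10 stratified is the package default.
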