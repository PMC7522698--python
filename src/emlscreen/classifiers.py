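"""The ten-model classifier bank behind one train/confidence contract.

Every base model — decision tree, PLS-DA, naive Bayes, random forest,
k-nearest neighbour, a one-hidden-layer neural network, an RBF support
vector machine with Platt scaling, linear discriminant analysis, logistic
regression, and a deeper multilayer perceptron — is exposed through the same
interface: fit on a labeled table, return an EC-membership confidence in
[0, 1] for any sample. Stratified k-fold cross-validation uses one seeded
fold partition shared by all models so their accuracies are comparable as
ensemble weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .table import LabeledFeatureTable, ValidationError, LABEL_EC, LABEL_CONTROL
from .preprocess import Preprocessor

MODEL_NAMES = (
    "decision_tree",
    "plsda",
    "naive_bayes",
    "random_forest",
    "knn",
    "ann",
    "svm",
    "lda",
    "logistic_regression",
    "deep_learning",
)


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA with Gaussian posteriors on the latent prediction.

    A PLS regression of the 0/1 class indicator on the intensity matrix
    yields a one-dimensional discriminant score; class-conditional normal
    densities fitted to the training scores give a posterior probability,
    so the model satisfies the bank's confidence contract.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError("PLSDAClassifier requires exactly two classes")
        ncomp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=ncomp, scale=False)
        y01 = (y == self.classes_[1]).astype(float)
        self.pls_.fit(X, y01)
        scores = self.pls_.predict(X).ravel()
        self.means_ = np.array([scores[y01 == c].mean() for c in (0.0, 1.0)])
        pooled = np.concatenate([scores[y01 == c] - self.means_[int(c)] for c in (0.0, 1.0)])
        self.sd_ = max(float(pooled.std(ddof=0)), 1e-9)
        self.priors_ = np.array([(y01 == 0).mean(), (y01 == 1).mean()])
        return self

    def decision_scores(self, X):
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()

    def predict_proba(self, X):
        s = self.decision_scores(X)
        logd = norm.logpdf(s[:, None], loc=self.means_[None, :], scale=self.sd_)
        logp = logd + np.log(self.priors_)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


@dataclass
class ClassifierSpec:
    """Name + hyperparameter overrides + seed for one base model."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValidationError(
                f"unknown model {self.name!r}; must be one of {MODEL_NAMES}")


def build_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for ``spec`` with defaults.

    Hyperparameters are unpublished in the source study; defaults here are
    conventional for metabolomic feature tables and all overridable via
    ``spec.hyperparams``.
    """
    hp = dict(spec.hyperparams)
    name, seed = spec.name, spec.seed
    if name == "decision_tree":
        return DecisionTreeClassifier(max_depth=5, random_state=seed, **hp)
    if name == "plsda":
        return PLSDAClassifier(**{"n_components": 5, **hp})
    if name == "naive_bayes":
        return GaussianNB(**hp)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed, **hp)
    if name == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **hp})
    if name == "ann":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                             random_state=seed, **hp)
    if name == "svm":
        # Platt scaling supplies the probability the margin alone lacks
        base = SVC(kernel="rbf", random_state=seed, **hp)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    if name == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000, **hp)
    if name == "deep_learning":
        return MLPClassifier(hidden_layer_sizes=(64, 32, 16), max_iter=500,
                             random_state=seed, **hp)
    raise ValidationError(f"unknown model {name!r}")  # pragma: no cover


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    estimator: object
    feature_ids: list[str]


def _check_trainable(table: LabeledFeatureTable) -> np.ndarray:
    if table.has_missing():
        raise ValidationError("training table contains missing values")
    y = table.y01()
    n_ec, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_ec < 2 or n_ctrl < 2:
        raise ValidationError(
            f"need >= 2 samples per class, got EC={n_ec}, control={n_ctrl}")
    return y


def train_classifier(spec: ClassifierSpec,
                     table: LabeledFeatureTable) -> TrainedClassifier:
    """Fit one base model on a fully labeled, preprocessed table."""
    y = _check_trainable(table)
    est = build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(table.values, y)
    return TrainedClassifier(spec=spec, estimator=est,
                             feature_ids=table.feature_ids)


def predict_confidence(model: TrainedClassifier,
                       table: LabeledFeatureTable) -> pd.DataFrame:
    """Per-sample predicted class and EC-membership confidence.

    The table must carry (a superset of) the features the model was trained
    on, already imputed and scaled with the training parameters. A sample is
    called EC iff its EC confidence strictly exceeds 0.5 (ties go to
    control). Output row order matches input sample order.
    """
    aligned = table.select_features(model.feature_ids)
    proba = model.estimator.predict_proba(aligned.values)
    # class encoding is 0=control, 1=EC throughout the bank
    p_ec = np.clip(proba[:, 1], 0.0, 1.0)
    pred = np.where(p_ec > 0.5, LABEL_EC, LABEL_CONTROL)
    return pd.DataFrame({
        "sample_id": aligned.sample_ids,
        "predicted_class": pred,
        "ec_confidence": p_ec,
    })


@dataclass
class CVResult:
    """Pooled held-out predictions of one model under stratified k-fold CV."""

    model_name: str
    k: int
    accuracy: float
    accuracy_se: float
    per_sample: pd.DataFrame = field(repr=False)  # sample_id, fold, true, pred, ec_confidence


def make_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold partition, shared across the whole bank."""
    counts = np.bincount(y, minlength=2)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(spec: ClassifierSpec, table: LabeledFeatureTable,
                   k: int = 10, seed: int = 0,
                   preprocessor: Preprocessor | None = None) -> CVResult:
    """Stratified k-fold CV accuracy with per-fold preprocessing refits.

    The fold partition depends only on (labels, k, seed), so every model in
    the bank sees identical folds. When a ``preprocessor`` template is
    given, imputation and scaling parameters are fitted on each training
    fold only and applied to its held-out fold — no leakage.
    """
    y = table.y01()
    folds = make_folds(y, k, seed)
    rows = []
    for fold_id, (tr, te) in enumerate(folds):
        train_t = table.subset_samples(tr)
        test_t = table.subset_samples(te)
        if preprocessor is not None:
            prep = preprocessor.clone_unfitted().fit(train_t)
            train_t = prep.transform(train_t)
            test_t = prep.transform(test_t)
        fitted = train_classifier(spec, train_t)
        out = predict_confidence(fitted, test_t)
        out.insert(1, "fold", fold_id)
        out.insert(2, "true_class", test_t.labels.to_numpy())
        rows.append(out)
    per_sample = pd.concat(rows, ignore_index=True)
    correct = (per_sample["predicted_class"] == per_sample["true_class"]).to_numpy()
    acc = float(correct.mean())
    se = float(np.sqrt(acc * (1 - acc) / len(correct)))
    return CVResult(model_name=spec.name, k=k, accuracy=acc,
                    accuracy_se=se, per_sample=per_sample)


def default_specs(seed: int = 0, hyperparams: dict[str, dict] | None = None
                  ) -> list[ClassifierSpec]:
    """One spec per bank member, seeds derived deterministically."""
    hyperparams = hyperparams or {}
    return [ClassifierSpec(name=n, hyperparams=hyperparams.get(n, {}),
                           seed=seed + i)
            for i, n in enumerate(MODEL_NAMES)]
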