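"""Accuracy-weighted ensemble voting and the signed EC-EML score.

The ensemble (EML) model holds the ten trained base classifiers, each
weighted by its cross-validation accuracy. For a screened sample every
member contributes a model score: its accuracy (on a 0-100 scale by
default) times the confidence of the class it predicted, negated when that
class is control. The EC-EML score is the sum of the ten model scores; a
positive value means the weighted votes favour EC. Class assignment uses
the normalized weighted EC-membership probability with a strict > 50% rule,
and a score-cutoff classifier (0 or a Youden-optimal cutoff) is provided as
the alternative decision device.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .table import LabeledFeatureTable, ValidationError, LABEL_EC, LABEL_CONTROL
from .preprocess import Preprocessor, FilterReport, filter_features
from .classifiers import (ClassifierSpec, CVResult, TrainedClassifier,
                          cross_validate, default_specs, predict_confidence,
                          train_classifier)

ACCURACY_SCALES = ("fraction", "percent")


def compute_model_score(cv_accuracy: float, confidence: float,
                        predicted_class: str,
                        accuracy_scale: str = "percent") -> float:
    """One member's signed vote: accuracy x predicted-class confidence.

    ``confidence`` is the probability of the class the member predicted;
    the product is negated when that class is control. On the default
    percent scale the accuracy enters as 100 x accuracy, so a unanimous
    ten-member ensemble spans [-1000, +1000].
    """
    if not 0 <= cv_accuracy <= 1:
        raise ValidationError(f"cv_accuracy must be in [0, 1], got {cv_accuracy}")
    if not 0 <= confidence <= 1:
        raise ValidationError(f"confidence must be in [0, 1], got {confidence}")
    if predicted_class not in (LABEL_EC, LABEL_CONTROL):
        raise ValidationError(f"predicted_class must be EC or control, got {predicted_class!r}")
    if accuracy_scale not in ACCURACY_SCALES:
        raise ValidationError(f"accuracy_scale must be one of {ACCURACY_SCALES}")
    w = cv_accuracy * 100.0 if accuracy_scale == "percent" else cv_accuracy
    s = w * confidence
    return s if predicted_class == LABEL_EC else -s


@dataclass
class EMLModel:
    """Fitted ensemble: members with CV-accuracy weights plus preprocessing."""

    members: list[tuple[TrainedClassifier, float]]
    preprocessor: Preprocessor
    keep_list: list[str]
    filter_report: FilterReport
    cv_results: dict[str, CVResult] = field(repr=False)
    accuracy_scale: str = "percent"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("an ensemble needs at least 2 members")
        for clf, w in self.members:
            if not 0 <= w <= 1:
                raise ValidationError(
                    f"cv_accuracy weight for {clf.spec.name} outside [0, 1]: {w}")
        if self.accuracy_scale not in ACCURACY_SCALES:
            raise ValidationError(f"accuracy_scale must be one of {ACCURACY_SCALES}")

    @property
    def member_names(self) -> list[str]:
        return [clf.spec.name for clf, _ in self.members]

    @property
    def weights(self) -> dict[str, float]:
        return {clf.spec.name: w for clf, w in self.members}


def fit_eml(table: LabeledFeatureTable,
            specs: list[ClassifierSpec] | None = None,
            k: int = 10, seed: int = 0,
            presence_threshold: float = 0.75,
            impute_strategy: str = "half_min",
            accuracy_scale: str = "percent") -> EMLModel:
    """Train the full ensemble on a labeled cohort.

    Pipeline: presence/variance filter -> per-model stratified k-fold CV on
    a shared seeded fold partition (imputation and scaling refitted inside
    each fold) to obtain the accuracy weights -> preprocessing refitted on
    the whole cohort -> every member refitted on the full preprocessed
    table. A member that fails to train aborts the fit.
    """
    specs = specs if specs is not None else default_specs(seed)
    filtered, report = filter_features(table, presence_threshold)
    template = Preprocessor(impute_strategy=impute_strategy)

    cv_results: dict[str, CVResult] = {}
    for spec in specs:
        cv_results[spec.name] = cross_validate(spec, filtered, k=k, seed=seed,
                                               preprocessor=template)

    prep = template.clone_unfitted().fit(filtered)
    processed = prep.transform(filtered)
    members = [(train_classifier(spec, processed), cv_results[spec.name].accuracy)
               for spec in specs]
    return EMLModel(members=members, preprocessor=prep,
                    keep_list=filtered.feature_ids, filter_report=report,
                    cv_results=cv_results, accuracy_scale=accuracy_scale)


def weighted_ec_probability(weights: np.ndarray, p_ec: np.ndarray) -> np.ndarray:
    """Normalized accuracy-weighted EC-membership probability.

    ``p_ec`` has one column per member; weights are the CV accuracies (the
    scale cancels). All-zero weights leave the probability undefined.
    """
    total = weights.sum()
    if total <= 0:
        raise ValidationError("all ensemble weights are zero")
    return (p_ec * weights).sum(axis=1) / total


def screen_cohort(model: EMLModel, table: LabeledFeatureTable) -> pd.DataFrame:
    """Apply the fitted ensemble to a cohort; labels are never read.

    Returns one row per sample: ``ec_eml_score`` (sum of signed member
    scores), ``weighted_ec_probability``, the ensemble class under the
    strict > 50% membership rule, and per-member ``score_<name>`` /
    ``p_ec_<name>`` columns.
    """
    data = table.select_features(model.keep_list)
    processed = model.preprocessor.transform(data)

    n = processed.n_samples
    names = model.member_names
    w = np.array([model.weights[m] for m in names])
    p_ec = np.empty((n, len(names)))
    scores = np.empty((n, len(names)))
    for j, (clf, acc) in enumerate(model.members):
        out = predict_confidence(clf, processed)
        p = out["ec_confidence"].to_numpy()
        p_ec[:, j] = p
        conf_pred = np.where(p > 0.5, p, 1 - p)
        sign = np.where(p > 0.5, 1.0, -1.0)
        w_scaled = acc * 100.0 if model.accuracy_scale == "percent" else acc
        scores[:, j] = sign * w_scaled * conf_pred

    wp = weighted_ec_probability(w, p_ec)
    result = pd.DataFrame({"sample_id": processed.sample_ids})
    result["ec_eml_score"] = scores.sum(axis=1)
    result["weighted_ec_probability"] = wp
    result["ensemble_class"] = np.where(wp > 0.5, LABEL_EC, LABEL_CONTROL)
    for j, name in enumerate(names):
        result[f"score_{name}"] = scores[:, j]
    for j, name in enumerate(names):
        result[f"p_ec_{name}"] = p_ec[:, j]
    return result


def classify_by_score(scores, cutoff: float = 0.0) -> np.ndarray:
    """EC iff ec_eml_score strictly exceeds ``cutoff`` (ties -> control).

    ``scores`` may be the DataFrame from :func:`screen_cohort` or a plain
    array of EC-EML scores. Cutoff 0 is the balanced-votes convention; a
    Youden-optimal cutoff from the evaluation module may be passed instead.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["ec_eml_score"].to_numpy()
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, LABEL_EC, LABEL_CONTROL)


def eml_cv_predictions(model: EMLModel) -> pd.DataFrame:
    """Ensemble-level held-out predictions on the training cohort.

    Because all members share one fold partition, their per-sample held-out
    EC confidences can be combined with the accuracy weights exactly as at
    screening time, yielding the ensemble's own cross-validated class calls.
    """
    names = model.member_names
    w = np.array([model.weights[m] for m in names])
    base = model.cv_results[names[0]].per_sample[["sample_id", "true_class"]]
    p = np.column_stack([
        model.cv_results[m].per_sample.set_index("sample_id")
        .loc[base["sample_id"], "ec_confidence"].to_numpy()
        for m in names
    ])
    wp = weighted_ec_probability(w, p)
    out = base.copy()
    out["weighted_ec_probability"] = wp
    out["predicted_class"] = np.where(wp > 0.5, LABEL_EC, LABEL_CONTROL)
    return out


# ---------------------------------------------------------------------------
# persistence


def save_eml(model: EMLModel, directory) -> None:
    """Persist the ensemble as a versioned bundle (joblib state + manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state_path = directory / "eml_state.joblib"
    joblib.dump(model, state_path)
    digest = hashlib.sha256(state_path.read_bytes()).hexdigest()
    manifest = {
        "format_version": 1,
        "members": [{"name": clf.spec.name, "seed": clf.spec.seed,
                     "hyperparams": clf.spec.hyperparams, "cv_accuracy": w}
                    for clf, w in model.members],
        "n_features": len(model.keep_list),
        "feature_ids": model.keep_list,
        "accuracy_scale": model.accuracy_scale,
        "state_sha256": digest,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_eml(directory) -> EMLModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    state_path = directory / "eml_state.joblib"
    digest = hashlib.sha256(state_path.read_bytes()).hexdigest()
    if digest != manifest["state_sha256"]:
        raise ValidationError("model bundle state does not match its manifest")
    return joblib.load(state_path)
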