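"""End-to-end orchestration: simulate -> train -> screen -> evaluate.

A :class:`RunConfig` (YAML-serializable) fixes every stage parameter and a
global seed from which all stage seeds derive, so a run is reproducible to
the byte. Screening-cohort labels enter only the evaluation stage; training,
screening and scoring never read them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .table import LabeledFeatureTable, ValidationError
from .cohort import CohortConfig, generate_cohort
from .classifiers import default_specs
from .ensemble import (EMLModel, classify_by_score, eml_cv_predictions,
                       fit_eml, save_eml, screen_cohort)
from .evaluation import (ConfusionCounts, performance_table, plsda_validate,
                         roc_analysis, screening_metrics)

logger = logging.getLogger("emlscreen")

CUTOFF_MODES = ("zero", "youden")


def _derived_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2 ** 31 - 1))


@dataclass
class RunConfig:
    """Full configuration of one screening study run."""

    training: CohortConfig
    screening: CohortConfig
    presence_threshold: float = 0.75
    impute_strategy: str = "half_min"
    hyperparams: dict = field(default_factory=dict)  # per-model overrides
    k_folds: int = 10
    n_permutations: int = 1000
    plsda_components: int = 5
    cutoff_mode: str = "zero"
    seed: int = 0
    outdir: str = "results"
    training_table: str | None = None   # CSV path replaces simulation
    screening_table: str | None = None

    def __post_init__(self) -> None:
        if self.cutoff_mode not in CUTOFF_MODES:
            raise ValidationError(f"cutoff_mode must be one of {CUTOFF_MODES}")
        if isinstance(self.training, dict):
            self.training = CohortConfig(**self.training)
        if isinstance(self.screening, dict):
            self.screening = CohortConfig(**self.screening)

    @classmethod
    def default(cls, seed: int = 0, outdir: str = "results") -> "RunConfig":
        """The demo world: 50/70 training, 1430-sample screening cohort at
        16/1430 ≈ 1.12% prevalence, 293 features with 25 below the presence
        rule."""
        return cls(
            training=CohortConfig(n_cases=50, n_controls=70,
                                  seed=_derived_seed(seed, 1)),
            screening=CohortConfig(n_cases=16, n_controls=1414,
                                   seed=_derived_seed(seed, 2)),
            seed=seed, outdir=outdir)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class RunArtifacts:
    outdir: Path
    model: EMLModel
    scores: "object"           # screening DataFrame
    metrics: dict              # evaluation results
    files: dict                # name -> path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_screening_study(config: RunConfig) -> RunArtifacts:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    t0 = time.time()

    def _stage(name):
        logger.info("stage %-10s t=%.1fs", name, time.time() - t0)

    try:
        _stage("simulate")
        if config.training_table:
            train_table = LabeledFeatureTable.from_csv(config.training_table)
        else:
            train_table = generate_cohort(config.training)
            train_table.to_csv(out / "training_table.csv")
            files["training_table"] = out / "training_table.csv"
        if config.screening_table:
            screen_table = LabeledFeatureTable.from_csv(config.screening_table)
        else:
            screen_table = generate_cohort(config.screening)
            screen_table.to_csv(out / "screening_table.csv")
            files["screening_table"] = out / "screening_table.csv"
        # truth labels are held back until the evaluation stage
        truth = screen_table.labels.copy()

        _stage("train")
        specs = default_specs(_derived_seed(config.seed, 3), config.hyperparams)
        model = fit_eml(train_table, specs=specs, k=config.k_folds,
                        seed=_derived_seed(config.seed, 4),
                        presence_threshold=config.presence_threshold,
                        impute_strategy=config.impute_strategy)
        save_eml(model, out / "model_bundle")
        files["model_bundle"] = out / "model_bundle"

        _stage("screen")
        scores = screen_cohort(model, screen_table)
        scores.to_csv(out / "scores.csv", index=False)
        files["scores"] = out / "scores.csv"

        _stage("evaluate")
        metrics = evaluate_run(model, scores, truth, train_table, config, out, files)
    except Exception as exc:  # noqa: BLE001 - stage-labeled abort
        raise RuntimeError(f"pipeline aborted (partial outputs in {out}): {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in files.items() if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    files["manifest"] = out / "manifest.json"
    _stage("done")
    return RunArtifacts(outdir=out, model=model, scores=scores,
                        metrics=metrics, files=files)


def evaluate_run(model: EMLModel, scores, truth, train_table, config: RunConfig,
                 out: Path, files: dict) -> dict:
    """Evaluation stage: the only consumer of screening-cohort labels."""
    roc = roc_analysis(scores["ec_eml_score"].to_numpy(), truth.to_numpy())
    roc.points().to_csv(out / "roc_points.csv", index=False)
    files["roc_points"] = out / "roc_points.csv"

    cutoff = 0.0 if config.cutoff_mode == "zero" else roc.youden_cutoff
    by_prob = scores["ensemble_class"].to_numpy()
    by_score = classify_by_score(scores, cutoff=cutoff)

    m_prob = screening_metrics(ConfusionCounts.from_labels(truth, by_prob))
    m_score = screening_metrics(ConfusionCounts.from_labels(truth, by_score))

    # training-side metrics from the shared held-out CV predictions
    rows = []
    for name, cv in model.cv_results.items():
        cm = ConfusionCounts.from_labels(cv.per_sample["true_class"],
                                         cv.per_sample["predicted_class"])
        rows.append(("training", name, screening_metrics(cm)))
    eml_cv = eml_cv_predictions(model)
    eml_train = screening_metrics(ConfusionCounts.from_labels(
        eml_cv["true_class"], eml_cv["predicted_class"]))
    rows.append(("training", "EML", eml_train))
    rows.append(("test", "EML", m_prob))
    report = performance_table(rows)
    report.to_csv(out / "performance_table.csv", index=False)
    files["performance_table"] = out / "performance_table.csv"

    # PLS-DA class-separation validation on the preprocessed training cohort
    processed = model.preprocessor.transform(
        train_table.select_features(model.keep_list))
    perm = plsda_validate(processed, n_components=config.plsda_components,
                          n_permutations=config.n_permutations,
                          seed=_derived_seed(config.seed, 5))

    metrics = {
        "roc": {"auc": roc.auc, "youden_cutoff": roc.youden_cutoff,
                "youden_j": roc.youden_j},
        "cutoff_mode": config.cutoff_mode,
        "cutoff": float(cutoff),
        "screening_by_probability": m_prob.as_dict(),
        "screening_by_score_cutoff": m_score.as_dict(),
        "eml_training_cv": eml_train.as_dict(),
        "cv_accuracies": {n: cv.accuracy for n, cv in model.cv_results.items()},
        "plsda_validation": {
            "r2y": perm.r2y, "q2y": perm.q2y,
            "n_permutations": perm.n_permutations,
            "observed_statistic": perm.observed_statistic,
            "p_value": perm.p_value,
        },
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    files["metrics"] = out / "metrics.json"
    return metrics
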