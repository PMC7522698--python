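"""Feature-table QC filtering, imputation and scaling.

Implements the 75%-presence retention rule (a feature must be observed in at
least the stated fraction of samples to survive), half-minimum / median
imputation of residual missing cells, and log + per-feature z-score scaling
with train/apply separation so screening cohorts are transformed with
training-set parameters only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import LabeledFeatureTable, ValidationError

IMPUTE_STRATEGIES = ("half_min", "feature_median")


@dataclass
class FilterReport:
    n_features_in: int
    n_features_kept: int
    dropped: list[tuple[str, str]]  # (feature_id, reason)
    presence_threshold: float

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "n_features_in": self.n_features_in,
            "n_features_kept": self.n_features_kept,
            "dropped": [list(d) for d in self.dropped],
            "presence_threshold": self.presence_threshold,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def filter_features(table: LabeledFeatureTable,
                    presence_threshold: float = 0.75
                    ) -> tuple[LabeledFeatureTable, FilterReport]:
    """Retain features observed in at least ``presence_threshold`` of samples.

    Features whose observed values are constant (zero variance) are also
    dropped — the computable stand-in for peaks of unusable quality. Column
    order of survivors is preserved; the rule never looks at labels.
    """
    if table.n_samples == 0 or table.n_features == 0:
        raise ValidationError("cannot filter an empty table")
    if not 0 < presence_threshold <= 1:
        raise ValidationError(
            f"presence_threshold must be in (0, 1], got {presence_threshold}")

    presence = table.data.notna().mean(axis=0)
    dropped: list[tuple[str, str]] = []
    keep: list[str] = []
    for fid in table.feature_ids:
        if presence[fid] < presence_threshold:
            dropped.append((fid, "low_presence"))
            continue
        observed = table.data[fid].dropna()
        if observed.nunique() <= 1:
            dropped.append((fid, "zero_variance"))
            continue
        keep.append(fid)
    report = FilterReport(table.n_features, len(keep), dropped, presence_threshold)
    return table.select_features(keep), report


def write_keep_list(report_table: LabeledFeatureTable, path) -> None:
    """Export the surviving feature ids, one per line, for reuse."""
    with open(path, "w") as fh:
        fh.write("\n".join(report_table.feature_ids) + "\n")


def fit_impute_params(table: LabeledFeatureTable,
                      strategy: str = "half_min") -> pd.Series:
    """Per-feature fill values from the observed cells of ``table``."""
    if strategy not in IMPUTE_STRATEGIES:
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    n_obs = table.data.notna().sum(axis=0)
    empty = list(table.data.columns[n_obs == 0])
    if empty:
        raise ValidationError(
            f"features with zero observed values (should have been filtered): {empty}")
    if strategy == "half_min":
        return table.data.min(axis=0, skipna=True) / 2.0
    return table.data.median(axis=0, skipna=True)


def impute_missing(table: LabeledFeatureTable, strategy: str = "half_min",
                   params: pd.Series | None = None) -> LabeledFeatureTable:
    """Replace missing cells; ``params`` reuses previously fitted fill values."""
    if params is None:
        params = fit_impute_params(table, strategy)
    if not table.has_missing():
        return table
    return LabeledFeatureTable(table.data.fillna(params), table.labels.copy())


@dataclass
class ScalingParams:
    log: bool
    mean: pd.Series
    sd: pd.Series = field(repr=False)


def scale_features(table: LabeledFeatureTable,
                   params: ScalingParams | None = None,
                   log: bool = True) -> tuple[LabeledFeatureTable, ScalingParams]:
    """Log-transform then standardize each feature to mean 0, sd 1.

    With ``params`` given (e.g. fitted on a training cohort) the stored means
    and sds are applied unchanged — the screening-cohort path. Otherwise
    parameters are fitted on ``table`` itself.
    """
    if table.has_missing():
        raise ValidationError("scale_features requires a fully imputed table")
    values = table.data
    use_log = params.log if params is not None else log
    if use_log:
        bad = values <= 0
        if bad.to_numpy().any():
            s, f = np.argwhere(bad.to_numpy())[0]
            raise ValidationError(
                f"non-positive intensity under log transform at sample "
                f"{table.sample_ids[s]!r}, feature {table.feature_ids[f]!r}")
        values = np.log(values)
    if params is None:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        zero = list(values.columns[sd == 0])
        if zero:
            raise ValidationError(
                f"constant features cannot be standardized (zero-variance rule): {zero}")
        params = ScalingParams(log=use_log, mean=mean, sd=sd)
    scaled = (values - params.mean) / params.sd
    return LabeledFeatureTable(scaled, table.labels.copy()), params


class Preprocessor:
    """Fit-on-train / apply-on-test bundle of imputation + scaling.

    Used inside every cross-validation fold (refit per fold, no leakage) and
    stored in the fitted ensemble for deployment on screening cohorts.
    """

    def __init__(self, impute_strategy: str = "half_min", log: bool = True):
        if impute_strategy not in IMPUTE_STRATEGIES:
            raise ValidationError(f"unknown imputation strategy {impute_strategy!r}")
        self.impute_strategy = impute_strategy
        self.log = log
        self.impute_params: pd.Series | None = None
        self.scaling_params: ScalingParams | None = None

    def fit(self, table: LabeledFeatureTable) -> "Preprocessor":
        self.impute_params = fit_impute_params(table, self.impute_strategy)
        imputed = impute_missing(table, params=self.impute_params)
        _, self.scaling_params = scale_features(imputed, log=self.log)
        return self

    def transform(self, table: LabeledFeatureTable) -> LabeledFeatureTable:
        if self.impute_params is None or self.scaling_params is None:
            raise ValidationError("Preprocessor is not fitted")
        table = table.select_features(list(self.impute_params.index))
        imputed = impute_missing(table, params=self.impute_params)
        scaled, _ = scale_features(imputed, params=self.scaling_params)
        return scaled

    def fit_transform(self, table: LabeledFeatureTable) -> LabeledFeatureTable:
        return self.fit(table).transform(table)

    def clone_unfitted(self) -> "Preprocessor":
        return Preprocessor(self.impute_strategy, self.log)
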