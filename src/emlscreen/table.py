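"""Labeled sample x metabolite feature tables.

The :class:`LabeledFeatureTable` is the universal currency of the pipeline:
a samples-by-features intensity matrix (``NaN`` marks a missing peak) with a
per-sample class label in ``{"EC", "control", "unknown"}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_EC = "EC"
LABEL_CONTROL = "control"
LABEL_UNKNOWN = "unknown"
VALID_LABELS = (LABEL_EC, LABEL_CONTROL, LABEL_UNKNOWN)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class LabeledFeatureTable:
    """Sample x feature intensity matrix with binary class labels.

    Parameters
    ----------
    data
        DataFrame indexed by sample id, one column per feature id. Missing
        intensities are ``NaN``.
    labels
        Series aligned to ``data.index`` with values ``"EC"``, ``"control"``
        or ``"unknown"``.
    """

    data: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature identifiers")
        self.labels = pd.Series(self.labels, dtype=object)
        if not self.labels.index.equals(self.data.index):
            if len(self.labels) != len(self.data):
                raise ValidationError("labels do not align with samples")
            self.labels.index = self.data.index
        bad = set(self.labels.unique()) - set(VALID_LABELS)
        if bad:
            raise ValidationError(f"invalid labels: {sorted(bad)}")

    # ---- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def y01(self) -> np.ndarray:
        """Labels encoded as 1 for EC, 0 for control; errors on unknown."""
        if (self.labels == LABEL_UNKNOWN).any():
            raise ValidationError("table contains 'unknown' labels")
        return (self.labels == LABEL_EC).to_numpy(dtype=int)

    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def select_features(self, feature_ids: list[str]) -> "LabeledFeatureTable":
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise ValidationError(f"missing required features: {missing}")
        return LabeledFeatureTable(self.data[feature_ids].copy(), self.labels.copy())

    def subset_samples(self, idx) -> "LabeledFeatureTable":
        return LabeledFeatureTable(self.data.iloc[idx].copy(), self.labels.iloc[idx].copy())

    # ---- serialization ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as CSV: ``sample_id`` column, ``label`` column, then features.

        Missing intensities become empty cells.
        """
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "sample_id"
        out.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "LabeledFeatureTable":
        frame = pd.read_csv(path, index_col="sample_id")
        if "label" not in frame.columns:
            raise ValidationError("CSV lacks a 'label' column")
        labels = frame.pop("label").astype(object)
        data = frame.astype(float)
        if (data.to_numpy() < 0).any():
            raise ValidationError("negative intensities in CSV input")
        return cls(data, labels)
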