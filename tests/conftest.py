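import numpy as np
import pandas as pd
import pytest

from emlscreen import CohortConfig, LabeledFeatureTable, generate_cohort


def make_table(values, labels, sample_ids=None, feature_ids=None) -> LabeledFeatureTable:
    """Build a LabeledFeatureTable from raw arrays (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j:03d}" for j in range(p)]
    data = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return LabeledFeatureTable(data, pd.Series(labels, index=sample_ids, dtype=object))


@pytest.fixture(scope="session")
def separable_cohort() -> LabeledFeatureTable:
    """Perfectly class-separated cohort: even one feature suffices."""
    cfg = CohortConfig(n_cases=30, n_controls=30, n_features=40, n_informative=10,
                       effect_size=8.0, low_presence_features=0, missing_rate=0.0,
                       seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> LabeledFeatureTable:
    """No class signal at all: any CV accuracy above chance is overfitting."""
    cfg = CohortConfig(n_cases=30, n_controls=30, n_features=40, n_informative=0,
                       effect_size=0.0, low_presence_features=0, missing_rate=0.0,
                       seed=12)
    return generate_cohort(cfg)
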