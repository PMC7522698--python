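"""Synthetic GC-MS-like case-control cohorts and demographic covariates.

The generator emulates the statistical structure a dried-blood-spot serum
metabolome screening study assumes: positive, right-skewed peak intensities
(log-normal), a class-separating mean shift on a configurable subset of
features, missing-at-random peak dropout, and a handful of low-presence
peaks engineered to fail the 75%-presence retention rule. Demographics
(pack-years, NCCN smoke-risk class) are generated independently of the
metabolome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .table import LabeledFeatureTable, ValidationError, LABEL_EC, LABEL_CONTROL

#: presence fraction targeted for engineered low-presence features; kept well
#: below the 0.75 retention rule so sampling noise cannot push them over it.
LOW_PRESENCE_TARGET = 0.5


@dataclass
class CohortConfig:
    """Parameters of one simulated case-control cohort.

    Defaults mirror the screening-study world the pipeline targets: 293 raw
    peaks of which 25 fall below the presence filter, log-normal intensities,
    and a class signal strong enough that the oracle linear rule is
    near-perfect (sqrt(30) * 1.2 / 2 ≈ 3.3 standard deviations).
    """

    n_cases: int
    n_controls: int
    n_features: int = 293
    n_informative: int = 30
    effect_size: float = 1.2
    base_log_mean: float = 12.0
    base_log_sd: float = 1.0
    missing_rate: float = 0.05
    low_presence_features: int = 25
    seed: int = 0
    missing_mode: str = "mcar"  # "mcar" | "censor" (intensity-dependent)
    block_size: int = 1  # >1 enables equicorrelated feature blocks
    block_rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_features", "n_informative",
                     "low_presence_features"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.effect_size < 0:
            raise ValidationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.base_log_sd <= 0:
            raise ValidationError(f"base_log_sd must be > 0, got {self.base_log_sd}")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.n_informative > self.n_features:
            raise ValidationError("n_informative exceeds n_features")
        if self.low_presence_features > self.n_features - self.n_informative:
            raise ValidationError(
                "low_presence_features exceeds n_features - n_informative")
        if self.missing_mode not in ("mcar", "censor"):
            raise ValidationError(f"missing_mode must be 'mcar' or 'censor', got {self.missing_mode!r}")
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")
        if not 0 <= self.block_rho < 1:
            raise ValidationError("block_rho must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


def _feature_rng(seed: int, stream: int, j: int) -> np.random.Generator:
    # One sub-stream per (purpose, feature column): adding features never
    # perturbs the values of earlier columns.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, j)))


def generate_cohort(config: CohortConfig) -> LabeledFeatureTable:
    """Simulate a labeled cohort per ``config``.

    Cases and controls share a per-feature log-normal intensity model; the
    first ``n_informative`` features carry an additive ``effect_size`` shift
    on the log scale in cases. The last ``low_presence_features`` features
    have their presence forced below the 75% retention threshold; all other
    features lose cells completely at random at ``missing_rate`` (or by
    left-censoring of low intensities in ``censor`` mode).

    Deterministic for a fixed config (including seed).
    """
    n = config.n_cases + config.n_controls
    if n == 0:
        raise ValidationError("n_cases + n_controls must be > 0")
    width = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    labels = pd.Series([LABEL_EC] * config.n_cases + [LABEL_CONTROL] * config.n_controls,
                       index=sample_ids, dtype=object)
    is_case = np.arange(n) < config.n_cases

    low_start = config.n_features - config.low_presence_features
    cols = np.empty((n, config.n_features), dtype=float)
    for j in range(config.n_features):
        z = _feature_rng(config.seed, 0, j).standard_normal(n)
        if config.block_size > 1 and config.block_rho > 0:
            factor = _feature_rng(config.seed, 2, j // config.block_size).standard_normal(n)
            z = math.sqrt(config.block_rho) * factor + math.sqrt(1 - config.block_rho) * z
        logx = config.base_log_mean + config.base_log_sd * z
        if j < config.n_informative:
            logx = logx + config.effect_size * is_case
        cols[:, j] = np.exp(logx)

    # missingness
    for j in range(config.n_features):
        rng = _feature_rng(config.seed, 1, j)
        if j >= low_start:
            k = int(np.ceil(n * (1 - LOW_PRESENCE_TARGET)))
            drop = rng.choice(n, size=k, replace=False)
            cols[drop, j] = np.nan
        elif config.missing_rate > 0:
            if config.missing_mode == "mcar":
                mask = rng.random(n) < config.missing_rate
            else:  # left-censoring: the lowest-intensity cells drop out
                cutoff = np.quantile(cols[:, j], config.missing_rate)
                mask = cols[:, j] <= cutoff
            cols[mask, j] = np.nan

    feature_ids = [f"M{j + 1:03d}" for j in range(config.n_features)]
    data = pd.DataFrame(cols, index=sample_ids, columns=feature_ids)
    return LabeledFeatureTable(data, labels)


def oracle_bayes_error(config: CohortConfig) -> float:
    """Closed-form error of the oracle linear rule at the class midpoint.

    With ``m`` informative features each shifted by ``d`` on a log scale of
    spread ``sigma``, the optimal linear statistic has between-class
    separation ``sqrt(m) * d / sigma`` and per-class error
    ``Phi(-sqrt(m) * d / (2 sigma))``.
    """
    from scipy.stats import norm

    delta = math.sqrt(config.n_informative) * config.effect_size / config.base_log_sd
    return float(norm.cdf(-delta / 2))


def oracle_classify(config: CohortConfig, table: LabeledFeatureTable) -> np.ndarray:
    """Apply the oracle linear rule (known informative set, known shift).

    Returns predicted labels; used as the generator's own ground-truth
    discriminant in calibration tests. Missing cells contribute zero
    evidence.
    """
    m = config.n_informative
    X = table.data.iloc[:, :m].to_numpy(dtype=float)
    centered = np.log(X) - (config.base_log_mean + config.effect_size / 2)
    score = np.nansum(centered, axis=1)
    return np.where(score > 0, LABEL_EC, LABEL_CONTROL)


# ---------------------------------------------------------------------------
# demographics


def pack_years(cigarettes_per_day: float, years_smoking: float) -> float:
    """Tobacco load: mean cigarettes per day x years of active smoking / 20."""
    if cigarettes_per_day < 0:
        raise ValidationError(f"cigarettes_per_day must be >= 0, got {cigarettes_per_day}")
    if years_smoking < 0:
        raise ValidationError(f"years_smoking must be >= 0, got {years_smoking}")
    return cigarettes_per_day * years_smoking / 20.0


RISK_CLASSES = ("low", "moderate", "high", "very_high")


def smoke_risk_class(age: float, pack_years: float, active: bool = False,
                     other_risk_factor: bool = False,
                     years_since_quit: float = 0.0) -> str:
    """NCCN smoke-related risk stratification, most-severe rule first.

    very_high: age >= 55 and >= 30 pack-years, unless quit > 15 years ago;
    high: age >= 50, >= 20 pack-years, active smoking plus another risk
    factor; moderate: age >= 50 and >= 20 pack-years; low: otherwise.
    """
    for name, v in (("age", age), ("pack_years", pack_years),
                    ("years_since_quit", years_since_quit)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    if age >= 55 and pack_years >= 30 and not years_since_quit > 15:
        return "very_high"
    if age >= 50 and pack_years >= 20 and active and other_risk_factor:
        return "high"
    if age >= 50 and pack_years >= 20:
        return "moderate"
    return "low"


@dataclass
class DemographicRecord:
    age: float
    cigarettes_per_day: float
    years_smoking: float
    active: bool
    other_risk_factor: bool
    years_since_quit: float
    pack_years: float = field(init=False)
    risk_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.pack_years = pack_years(self.cigarettes_per_day, self.years_smoking)
        self.risk_class = smoke_risk_class(
            self.age, self.pack_years, self.active,
            self.other_risk_factor, self.years_since_quit)


def generate_demographics(n: int, seed: int = 0) -> pd.DataFrame:
    """Simulate demographic covariates for ``n`` postmenopausal women.

    Ages are drawn around a screening-population mean of 59.7 (SD 7.7) years
    truncated to the 50-80 inclusion window; roughly a quarter currently
    smoke and a sixth formerly smoked, with pack-year loads centred near the
    mid-teens. Independent of the metabolome by design.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    age = np.clip(rng.normal(59.7, 7.7, n), 50.0, 80.0)
    u = rng.random(n)
    current = u < 0.244
    former = (u >= 0.244) & (u < 0.244 + 0.175)
    ever = current | former
    cigs = np.where(ever, np.clip(rng.normal(15.0, 8.0, n), 1.0, 60.0), 0.0)
    years = np.where(ever, np.clip(rng.normal(20.0, 10.0, n), 1.0, None), 0.0)
    years = np.minimum(years, np.maximum(age - 18.0, 1.0))
    quit = np.where(former, rng.uniform(1.0, 25.0, n), 0.0)
    other = rng.random(n) < 0.10

    records = [
        DemographicRecord(age=float(age[i]), cigarettes_per_day=float(cigs[i]),
                          years_smoking=float(years[i]), active=bool(current[i]),
                          other_risk_factor=bool(other[i]),
                          years_since_quit=float(quit[i]))
        for i in range(n)
    ]
    return pd.DataFrame([asdict(r) for r in records])
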