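"""Diagnostic-performance evaluation.

Confusion-matrix screening metrics (sensitivity, specificity, PPV, NPV,
likelihood ratios, accuracy with binomial standard errors), ROC analysis
with the Youden-optimal cutoff, the DeLong placement-value test for
correlated AUCs, PLS-DA permutation validation (R2Y / Q2Y and a
separation-distance null), and a Table-2-shaped performance report.
Undefined ratios (zero denominators) are reported as missing and rendered
"ND", never coerced to 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .table import LabeledFeatureTable, ValidationError, LABEL_EC

PROPORTION_METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty (total = 0)")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, true_labels, predicted_labels,
                    positive: str = LABEL_EC) -> "ConfusionCounts":
        t = np.asarray(true_labels) == positive
        p = np.asarray(predicted_labels) == positive
        return cls(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                   fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


@dataclass
class ScreeningMetrics:
    """The seven diagnostic indices plus prevalence and binomial SEs.

    ``None`` marks an undefined metric (zero denominator). Standard errors
    use sqrt(p (1-p) / n) on each proportion's own denominator.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    lr_pos: float | None
    lr_neg: float | None
    prevalence: float
    se: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in PROPORTION_METRICS}
        d.update(lr_pos=self.lr_pos, lr_neg=self.lr_neg, prevalence=self.prevalence)
        d["se"] = dict(self.se)
        d["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn, "tn": self.counts.tn}
        return d


def screening_metrics(counts: ConfusionCounts) -> ScreeningMetrics:
    """Derive the screening indices from a confusion matrix.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); ppv = tp/(tp+fp);
    npv = tn/(tn+fn); accuracy = (tp+tn)/total; LR+ = sens/(1-spec);
    LR- = (1-sens)/spec; prevalence = (tp+fn)/total. A metric whose
    denominator is zero is undefined (None), matching the "ND" convention.
    """
    c = counts
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    acc = (c.tp + c.tn) / c.total
    lr_pos = None if spec is None or spec == 1 or sens is None else sens / (1 - spec)
    lr_neg = None if spec is None or spec == 0 or sens is None else (1 - sens) / spec

    denoms = {"sensitivity": c.tp + c.fn, "specificity": c.tn + c.fp,
              "ppv": c.tp + c.fp, "npv": c.tn + c.fn, "accuracy": c.total}
    values = {"sensitivity": sens, "specificity": spec, "ppv": ppv,
              "npv": npv, "accuracy": acc}
    se = {m: (None if values[m] is None else
              float(np.sqrt(values[m] * (1 - values[m]) / denoms[m])))
          for m in PROPORTION_METRICS}
    return ScreeningMetrics(counts=c, sensitivity=sens, specificity=spec,
                            ppv=ppv, npv=npv, accuracy=acc, lr_pos=lr_pos,
                            lr_neg=lr_neg, prevalence=(c.tp + c.fn) / c.total,
                            se=se)


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass
class ROCAnalysis:
    thresholds: np.ndarray  # candidate cutoffs for the rule score > t
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc_analysis(scores, labels) -> ROCAnalysis:
    """ROC curve, trapezoidal AUC, and the Youden-optimal cutoff.

    Higher scores are more EC-like; the decision rule is ``score > t``.
    Candidate cutoffs are the midpoints between consecutive distinct scores
    (plus one below the minimum and the maximum itself), so every
    achievable operating point is swept. The Youden cutoff maximizes
    J = sensitivity + specificity - 1, ties broken toward higher
    specificity. The trapezoidal AUC over these points equals the
    Mann-Whitney rank statistic (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == LABEL_EC if np.asarray(labels).dtype.kind in "OUS" \
        else np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for ROC analysis")

    uniq = np.unique(scores)  # ascending
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    # positives for rule score > t: counts of case/control scores above t
    pos_sorted = np.sort(scores[y])
    neg_sorted = np.sort(scores[~y])
    tp = n_pos - np.searchsorted(pos_sorted, cuts, side="right")
    fp = n_neg - np.searchsorted(neg_sorted, cuts, side="right")
    tpr = tp / n_pos
    fpr = fp / n_neg

    # cuts ascend, so tpr/fpr descend from (1,1) to (0,0); reversing the
    # sweep yields the ROC curve with both coordinates non-decreasing
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j == best_j)
    best = candidates[np.argmin(fpr[candidates])]
    return ROCAnalysis(thresholds=cuts, fpr=fpr, tpr=tpr, auc=auc,
                       youden_cutoff=float(cuts[best]), youden_j=float(best_j))


# ---------------------------------------------------------------------------
# DeLong


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per case) and V01 (per control), and the AUC."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z: float  # NaN when the variance of the difference degenerates
    p_value: float


def delong_test(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong placement-value comparison of two correlated AUCs.

    Both score vectors refer to the same samples. Variances and the
    covariance come from the empirical (co)variance of the per-case and
    per-control placement values; z = (AUC_a - AUC_b) / sqrt(var_a + var_b
    - 2 cov) with a two-sided normal p-value. Identical scores (or any
    degenerate variance of the difference) yield z = NaN unless the AUC
    difference is exactly zero, in which case p = 1.
    """
    labels = np.asarray(labels)
    y = labels == LABEL_EC if labels.dtype.kind in "OUS" else labels.astype(bool)
    a, b = np.asarray(scores_a, dtype=float), np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise ValidationError("scores_a, scores_b and labels must be aligned")
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValidationError("both classes must be present")

    v10a, v01a, auc_a = _placements(a[y], a[~y])
    v10b, v01b, auc_b = _placements(b[y], b[~y])

    def _var(v10, v01):
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        return s10 / m + s01 / n

    def _cov():
        c10 = np.cov(v10a, v10b, ddof=1)[0, 1] if m > 1 else 0.0
        c01 = np.cov(v01a, v01b, ddof=1)[0, 1] if n > 1 else 0.0
        return c10 / m + c01 / n

    var_a, var_b, cov = _var(v10a, v01a), _var(v10b, v01b), _cov()
    var_diff = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = np.nan
        p = 1.0 if diff == 0 else np.nan
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * (1 - norm.cdf(abs(z))))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, variance_a=float(var_a),
                            variance_b=float(var_b), covariance=float(cov),
                            z=float(z), p_value=p)


def auc_variance(scores, labels) -> tuple[float, float]:
    """DeLong variance of a single AUC; returns (auc, variance)."""
    cmp = delong_test(scores, scores, labels)
    return cmp.auc_a, cmp.variance_a


# ---------------------------------------------------------------------------
# PLS-DA permutation validation


@dataclass
class PermutationValidation:
    r2y: float
    q2y: float
    n_components: int
    n_permutations: int
    observed_statistic: float
    permuted_statistics: np.ndarray = field(repr=False)
    p_value: float


def _separation_distance(T: np.ndarray, y: np.ndarray) -> float:
    """Distance between class centroids in latent space over pooled spread."""
    mu1, mu0 = T[y == 1].mean(axis=0), T[y == 0].mean(axis=0)
    resid = np.concatenate([T[y == 1] - mu1, T[y == 0] - mu0])
    pooled = np.sqrt((resid ** 2).sum() / max(len(y) - 2, 1))
    if pooled == 0:
        return np.inf
    return float(np.linalg.norm(mu1 - mu0) / pooled)


def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual can deconverge on permuted labels
        pls.fit(X, y.astype(float))
    return pls


def plsda_validate(table: LabeledFeatureTable, n_components: int = 5,
                   n_permutations: int = 1000, seed: int = 0,
                   q2_folds: int = 7) -> PermutationValidation:
    """PLS-DA class-separation validation by label permutation.

    R2Y is the in-fit fraction of label variance explained; Q2Y the
    cross-validated (``q2_folds``-fold) analogue. The test statistic is the
    between-class centroid distance in the latent score space scaled by the
    pooled within-class spread; the null is built by refitting on permuted
    labels, and p = (1 + #{permuted >= observed}) / (n_permutations + 1).
    """
    if table.has_missing():
        raise ValidationError("plsda_validate requires an imputed table")
    X = table.values
    y = table.y01()
    if n_components >= min(X.shape[0], X.shape[1] + 1):
        raise ValidationError(
            f"n_components={n_components} too large for table of shape {X.shape}")
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValidationError("both classes must be present")

    yc = y.astype(float)
    ss_tot = ((yc - yc.mean()) ** 2).sum()
    pls = _fit_pls(X, y, n_components)
    resid = yc - pls.predict(X).ravel()
    r2y = 1 - (resid ** 2).sum() / ss_tot

    press = 0.0
    kf = KFold(n_splits=q2_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        fold = _fit_pls(X[tr], y[tr], n_components)
        press += ((yc[te] - fold.predict(X[te]).ravel()) ** 2).sum()
    q2y = 1 - press / ss_tot

    observed = _separation_distance(pls.x_scores_, y)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        fit = _fit_pls(X, yp, n_components)
        permuted[b] = _separation_distance(fit.x_scores_, yp)
    p = (1 + int((permuted >= observed).sum())) / (n_permutations + 1)
    return PermutationValidation(r2y=float(r2y), q2y=float(q2y),
                                 n_components=n_components,
                                 n_permutations=n_permutations,
                                 observed_statistic=observed,
                                 permuted_statistics=permuted, p_value=p)


# ---------------------------------------------------------------------------
# Table-2-shaped report


def _fmt_pct(v: float | None, nd: str = "ND") -> str:
    return nd if v is None else f"{100 * v:.1f}"


def _fmt_lr(v: float | None, decimals: int) -> str:
    return "ND" if v is None else f"{v:.{decimals}f}"


def performance_table(rows: list[tuple[str, str, ScreeningMetrics]]) -> pd.DataFrame:
    """Render (enrollment, model, metrics) rows as a diagnostic report.

    Columns mirror the study-report layout: percentages (with SE in
    percentage points) to one decimal, LR+ to one decimal, LR- to two,
    undefined ratios as "ND".
    """
    out = []
    for enrollment, model_name, m in rows:
        out.append({
            "enrollment": enrollment,
            "model": model_name,
            "sensitivity": _fmt_pct(m.sensitivity),
            "sensitivity_se": _fmt_pct(m.se["sensitivity"]),
            "specificity": _fmt_pct(m.specificity),
            "specificity_se": _fmt_pct(m.se["specificity"]),
            "ppv": _fmt_pct(m.ppv),
            "ppv_se": _fmt_pct(m.se["ppv"]),
            "npv": _fmt_pct(m.npv),
            "npv_se": _fmt_pct(m.se["npv"]),
            "lr_pos": _fmt_lr(m.lr_pos, 1),
            "lr_neg": _fmt_lr(m.lr_neg, 2),
            "accuracy": _fmt_pct(m.accuracy),
        })
    return pd.DataFrame(out)
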