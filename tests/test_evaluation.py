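"""Screening metrics, ROC/Youden, DeLong, and PLS-DA permutation validation,
each checked against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emlscreen import (CohortConfig, ConfusionCounts, ValidationError,
                       auc_variance, delong_test, generate_cohort,
                       performance_table, plsda_validate, roc_analysis,
                       screening_metrics)
from emlscreen.preprocess import Preprocessor, filter_features

from conftest import make_table


# ---------------------------------------------------------------------------
# confusion metrics


def test_paper_style_test_set_counts():
    """18 positives of which 16 confirmed, no false negatives, n = 1430."""
    m = screening_metrics(ConfusionCounts(tp=16, fp=2, fn=0, tn=1412))
    assert m.sensitivity == 1.0
    assert m.npv == 1.0
    assert m.ppv == pytest.approx(16 / 18)
    assert round(100 * m.ppv, 1) == 88.9
    assert m.accuracy == pytest.approx(1428 / 1430)
    assert round(100 * m.accuracy, 2) == 99.86
    assert m.lr_pos == pytest.approx(707.0)
    assert m.lr_neg == 0.0
    assert round(100 * m.prevalence, 2) == 1.12


def test_perfect_test_has_undefined_lr_pos():
    m = screening_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
    for v in (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy):
        assert v == 1.0
    assert m.lr_pos is None  # division by zero reported as undefined, not inf
    assert m.lr_neg == 0.0


def test_empty_matrix_rejected():
    with pytest.raises(ValidationError):
        ConfusionCounts(0, 0, 0, 0)
    with pytest.raises(ValidationError):
        ConfusionCounts(-1, 1, 1, 1)


@given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                 st.integers(0, 200), st.integers(0, 200))
       .filter(lambda c: sum(c) > 0))
@settings(deadline=None, derandomize=True, max_examples=300)
def test_metrics_match_first_principles(counts):
    """Independent recomputation of every index from the raw counts."""
    tp, fp, fn, tn = counts
    m = screening_metrics(ConfusionCounts(tp, fp, fn, tn))
    total = tp + fp + fn + tn

    def safe(num, den):
        return None if den == 0 else num / den

    assert m.sensitivity == safe(tp, tp + fn)
    assert m.specificity == safe(tn, tn + fp)
    assert m.ppv == safe(tp, tp + fp)
    assert m.npv == safe(tn, tn + fn)
    assert m.accuracy == (tp + tn) / total
    assert m.prevalence == (tp + fn) / total
    if m.sensitivity is not None and m.specificity not in (None, 1):
        assert m.lr_pos == pytest.approx(m.sensitivity / (1 - m.specificity))
    else:
        assert m.lr_pos is None
    for name, v in [("sensitivity", m.sensitivity), ("accuracy", m.accuracy)]:
        if v is not None:
            assert 0 <= v <= 1
            assert m.se[name] >= 0


def test_confusion_from_labels():
    truth = ["EC", "EC", "control", "control", "control"]
    pred = ["EC", "control", "EC", "control", "control"]
    c = ConfusionCounts.from_labels(truth, pred)
    assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 2)


# ---------------------------------------------------------------------------
# ROC / Youden


def _mann_whitney_auc(scores, labels):
    """Exhaustive pair-count oracle: P(case > control) + half ties."""
    pos = scores[np.asarray(labels) == "EC"]
    neg = scores[np.asarray(labels) == "control"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfectly_separated_scores():
    scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = ["control"] * 3 + ["EC"] * 3
    roc = roc_analysis(scores, labels)
    assert roc.auc == 1.0
    assert roc.youden_j == 1.0
    assert 3.0 < roc.youden_cutoff < 10.0  # strictly between the groups


def test_null_scores_auc_near_half():
    rng = np.random.default_rng(8)
    scores = rng.normal(0, 1, 2000)
    labels = np.where(rng.random(2000) < 0.5, "EC", "control")
    roc = roc_analysis(scores, labels)
    assert abs(roc.auc - 0.5) <= 0.04


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_mann_whitney_pair_count(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    # round to one decimal to force ties
    scores = np.round(rng.normal(0, 1, n), 1)
    labels = np.array(["EC"] * (n // 3 + 1) + ["control"] * (n - n // 3 - 1))
    scores[labels == "EC"] += 0.5
    roc = roc_analysis(scores, labels)
    assert roc.auc == pytest.approx(_mann_whitney_auc(scores, labels))


def test_roc_monotone_and_transform_invariant():
    rng = np.random.default_rng(9)
    scores = rng.normal(0, 1, 120)
    labels = np.where(np.arange(120) < 40, "EC", "control")
    scores[:40] += 1.0
    roc = roc_analysis(scores, labels)
    # thresholds ascend, so the curve read backwards runs (0,0) -> (1,1)
    assert (np.diff(roc.fpr[::-1]) >= 0).all()
    assert (np.diff(roc.tpr[::-1]) >= 0).all()
    for transform in (np.exp, lambda s: s ** 3, lambda s: 2 * s + 7):
        assert roc_analysis(transform(scores), labels).auc == pytest.approx(roc.auc)


@pytest.mark.parametrize("seed", range(4))
def test_youden_sweep_equals_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    n = 150
    labels = np.where(np.arange(n) < 60, "EC", "control")
    scores = rng.normal(0, 1, n) + (labels == "EC") * 1.2
    roc = roc_analysis(scores, labels)
    # brute force over all midpoints plus outer sentinels
    uniq = np.sort(np.unique(scores))
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1]]])
    best = -np.inf
    for t in cands:
        pred = scores > t
        sens = pred[labels == "EC"].mean()
        spec = 1 - pred[labels == "control"].mean()
        best = max(best, sens + spec - 1)
    assert roc.youden_j == pytest.approx(best)
    # and the reported cutoff achieves that J
    pred = scores > roc.youden_cutoff
    j_at = pred[labels == "EC"].mean() + (1 - pred[labels == "control"].mean()) - 1
    assert j_at == pytest.approx(roc.youden_j)


def test_roc_requires_both_classes():
    with pytest.raises(ValidationError):
        roc_analysis(np.arange(5.0), ["EC"] * 5)


# ---------------------------------------------------------------------------
# DeLong


def test_delong_identical_scores():
    rng = np.random.default_rng(10)
    labels = np.where(np.arange(60) < 20, "EC", "control")
    s = rng.normal(0, 1, 60) + (labels == "EC")
    cmp = delong_test(s, s, labels)
    assert cmp.auc_a == cmp.auc_b
    assert cmp.p_value == 1.0


def test_delong_label_swap_negates_z():
    rng = np.random.default_rng(11)
    labels = np.where(np.arange(80) < 30, "EC", "control")
    a = rng.normal(0, 1, 80) + (labels == "EC") * 1.5
    b = rng.normal(0, 1, 80) + (labels == "EC") * 0.5
    fwd = delong_test(a, b, labels)
    rev = delong_test(-a, -b, labels)  # negated scores flip both AUCs
    assert rev.z == pytest.approx(-fwd.z)
    assert rev.p_value == pytest.approx(fwd.p_value)
    assert fwd.p_value < 0.05  # clearly different discriminators


def test_delong_variance_matches_bootstrap():
    """Placement-value variance vs 2000 stratified bootstrap resamples."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(12)
    n = 100
    pos = rng.normal(1.0, 1, n)
    neg = rng.normal(0.0, 1, n)
    scores = np.concatenate([pos, neg])
    labels = np.array(["EC"] * n + ["control"] * n)
    auc, var = auc_variance(scores, labels)

    def fast_auc(p, q):
        r = rankdata(np.concatenate([p, q]))
        return (r[:len(p)].sum() - len(p) * (len(p) + 1) / 2) / (len(p) * len(q))

    boots = np.array([
        fast_auc(pos[rng.integers(0, n, n)], neg[rng.integers(0, n, n)])
        for _ in range(2000)
    ])
    assert abs(var - boots.var(ddof=1)) / boots.var(ddof=1) <= 0.15


# ---------------------------------------------------------------------------
# PLS-DA permutation validation


def _processed(cfg):
    t = generate_cohort(cfg)
    filtered, _ = filter_features(t)
    return Preprocessor().fit_transform(filtered)


def test_separated_cohort_reaches_minimal_p():
    cfg = CohortConfig(n_cases=30, n_controls=30, n_features=40, n_informative=10,
                       effect_size=5.0, low_presence_features=0,
                       missing_rate=0.0, seed=14)
    res = plsda_validate(_processed(cfg), n_components=5, n_permutations=199,
                        seed=1)
    assert res.p_value == pytest.approx(1 / 200)
    assert res.r2y > 0.8
    assert res.q2y > 0.8


def test_q2_never_beats_r2():
    """Cross-validated fit cannot exceed the in-sample fit."""
    for seed in range(6):
        cfg = CohortConfig(n_cases=20, n_controls=20, n_features=30,
                           n_informative=5, effect_size=float(seed % 3),
                           low_presence_features=0, missing_rate=0.0, seed=seed)
        res = plsda_validate(_processed(cfg), n_components=3, n_permutations=5,
                            seed=seed)
        assert res.q2y <= res.r2y + 1e-9


def test_plsda_component_guard():
    cfg = CohortConfig(n_cases=5, n_controls=5, n_features=4, n_informative=2,
                       low_presence_features=0, missing_rate=0.0, seed=15)
    with pytest.raises(ValidationError, match="n_components"):
        plsda_validate(_processed(cfg), n_components=40)


# ---------------------------------------------------------------------------
# report


def test_performance_table_formats_and_round_trips(tmp_path):
    import pandas as pd

    m_test = screening_metrics(ConfusionCounts(16, 2, 0, 1412))
    m_perfect = screening_metrics(ConfusionCounts(10, 0, 0, 10))
    table = performance_table([("test", "EML", m_test),
                               ("training", "knn", m_perfect)])
    row = table.iloc[0]
    assert row["lr_pos"] == "707.0"
    assert row["accuracy"] == "99.9"
    assert row["lr_neg"] == "0.00"
    assert table.iloc[1]["lr_pos"] == "ND"

    path = tmp_path / "report.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path, dtype=str)
    parsed = float(back.iloc[0]["sensitivity"])
    assert parsed == round(100 * m_test.sensitivity, 1)
    assert float(back.iloc[0]["ppv"]) == round(100 * m_test.ppv, 1)
    assert back.iloc[1]["lr_pos"] == "ND"
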