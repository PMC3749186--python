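"""Mann-Whitney AUC, confidence intervals, paired comparison, grader curves.

Oracles: a brute-force O(n_pos * n_neg) pairwise count for the AUC, explicit
double-loop structural components for the DeLong variance, a sign-flip
permutation reference for the paired test, and exact binomial enumeration
for the aggregation-gain curve.
"""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crowdroc import (
    auc_ci,
    auc_vs_k,
    binary_auc,
    build_manifest,
    calibration_preset,
    correlated_auc_test,
    mw_auc,
    scores_from_dataset,
    simulate_study,
)


def brute_force_auc(scores, labels):
    """Direct pairwise count: concordant pairs plus half the ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
    )
    return total / (len(pos) * len(neg))


@st.composite
def scored_sample(draw):
    n_pos = draw(st.integers(1, 50))
    n_neg = draw(st.integers(1, 50))
    # coarse integer scores force plenty of ties
    pos = draw(st.lists(st.integers(0, 8), min_size=n_pos, max_size=n_pos))
    neg = draw(st.lists(st.integers(0, 8), min_size=n_neg, max_size=n_neg))
    return pos + neg, [True] * n_pos + [False] * n_neg


@settings(max_examples=150, deadline=None, derandomize=True)
@given(scored_sample())
def test_mw_auc_equals_brute_force_pairwise(sample):
    scores, labels = sample
    assert mw_auc(scores, labels) == pytest.approx(
        brute_force_auc(scores, labels), abs=1e-12
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(scored_sample())
def test_label_flip_symmetry(sample):
    scores, labels = sample
    flipped = [not l for l in labels]
    assert mw_auc(scores, labels) + mw_auc(scores, flipped) == pytest.approx(1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(scored_sample())
def test_monotone_transform_invariance(sample):
    scores, labels = sample
    base = mw_auc(scores, labels)
    for f in (lambda x: 3.0 * x + 1.0, math.exp, math.atan):
        assert mw_auc([f(s) for s in scores], labels) == pytest.approx(base)


def test_mw_auc_edge_cases():
    assert mw_auc([1, 1, 0, 0], [True, True, False, False]) == 1.0
    assert mw_auc([5, 5, 5, 5], [True, True, False, False]) == 0.5
    with pytest.raises(ValueError, match="at least one"):
        mw_auc([1, 2], [True, True])


def test_mw_auc_agrees_with_sklearn_on_continuous_scores():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    labels = rng.random(300) < 0.4
    scores = rng.normal(labels.astype(float), 1.0)
    assert mw_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


@pytest.mark.parametrize(
    "sens,spec,expected",
    [(0.98, 0.85, 0.915), (0.96, 0.86, 0.91), (1.0, 1.0, 1.0)],
)
def test_binary_auc_values(sens, spec, expected):
    assert binary_auc(sens, spec) == pytest.approx(expected, abs=1e-12)


def test_binary_auc_identity_with_mann_whitney():
    """(sens+spec)/2 equals mw_auc on binary per-vote predictions exactly."""
    # 200 abnormal votes at sensitivity 0.98, 600 normal votes at specificity 0.85
    scores = [1] * 196 + [0] * 4 + [1] * 90 + [0] * 510
    labels = [True] * 200 + [False] * 600
    assert mw_auc(scores, labels) == pytest.approx(binary_auc(0.98, 0.85), abs=1e-12)


def test_auc_ci_clips_to_unit_interval():
    r = auc_ci([1, 1, 0, 0], [True, True, False, False], method="hanley_mcneil")
    assert r.auc == 1.0
    assert r.ci_high == 1.0


def test_delong_variance_matches_double_loop_oracle():
    rng = np.random.default_rng(4)
    labels = rng.random(500) < 0.5
    scores = rng.integers(0, 12, size=500).astype(float)  # ties included

    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    v10 = np.array([np.mean((b < a) + 0.5 * (b == a)) for a, b in
                    ((a, neg) for a in pos)])
    v01 = np.array([np.mean((pos > b) + 0.5 * (pos == b)) for b in neg])
    var_oracle = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    auc_oracle = v10.mean()

    r = auc_ci(scores, labels, method="delong")
    half = r.ci_high - r.auc
    assert r.auc == pytest.approx(auc_oracle, abs=1e-12)
    assert half == pytest.approx(1.959963985 * math.sqrt(var_oracle), abs=1e-9)


@pytest.mark.parametrize("method", ["hanley_mcneil", "delong"])
def test_ci_width_scales_inverse_sqrt_n(method):
    rng = np.random.default_rng(8)
    widths = {}
    for n in (100, 400, 1600):
        labels = np.arange(n) < n // 2
        scores = rng.normal(labels.astype(float), 1.0)
        r = auc_ci(scores, labels, method=method)
        widths[n] = r.ci_high - r.ci_low
    assert 1.5 < widths[100] / widths[400] < 2.7
    assert 1.5 < widths[400] / widths[1600] < 2.7


def test_delong_ci_coverage_near_nominal():
    """~95% of DeLong intervals cover the true binormal AUC at n = 2000."""
    rng = np.random.default_rng(12)
    delta = 1.0
    true_auc = stats.norm.cdf(delta / math.sqrt(2))
    n_sims, covered = 300, 0
    labels = np.arange(2000) < 1000
    for _ in range(n_sims):
        scores = rng.normal(labels.astype(float) * delta, 1.0)
        r = auc_ci(scores, labels, method="delong")
        covered += r.ci_low <= true_auc <= r.ci_high
    assert 0.92 <= covered / n_sims <= 0.98


def test_correlated_test_identical_scores_is_null():
    rng = np.random.default_rng(1)
    labels = rng.random(80) < 0.5
    scores = rng.normal(size=80)
    z, p = correlated_auc_test(scores, scores, labels)
    assert (z, p) == (0.0, 1.0)
    with pytest.raises(ValueError, match="equal lengths"):
        correlated_auc_test(scores, scores[:-1], labels)


def test_correlated_test_against_permutation_oracle():
    """DeLong p agrees with a sign-flip permutation reference."""
    rng = np.random.default_rng(21)
    n = 60
    labels = np.arange(n) < n // 2
    base = rng.normal(labels.astype(float), 1.0)
    scores_a = base + rng.normal(0, 0.6, n) + 0.25 * labels
    scores_b = base + rng.normal(0, 0.6, n)

    def diff(a, b):
        return mw_auc(a, labels) - mw_auc(b, labels)

    observed = abs(diff(scores_a, scores_b))
    n_perm, hits = 1000, 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        a = np.where(swap, scores_b, scores_a)
        b = np.where(swap, scores_a, scores_b)
        hits += abs(diff(a, b)) >= observed - 1e-12
    p_perm = hits / n_perm
    _, p_delong = correlated_auc_test(scores_a, scores_b, labels)
    assert abs(p_delong - p_perm) < 0.12


def test_design_comparison_detects_simulated_accuracy_gap(paper_manifest):
    """Design 3's higher specificity yields a significantly higher AUC than
    design 1 when both crowds grade the same images (paired by vote slot)."""
    cfg3 = calibration_preset("0.03c_500_90", 1)
    cfg1 = calibration_preset("0.03c", 1)
    scores_a, scores_b, labels = [], [], []
    for seed in (101, 102, 103):  # three replicate studies, pooled
        ds3 = simulate_study(cfg3, paper_manifest, seed=seed)
        ds1 = simulate_study(cfg1, paper_manifest, seed=seed + 500)
        s3, l3 = scores_from_dataset(ds3, "per_classification")
        s1, l1 = scores_from_dataset(ds1, "per_classification")
        assert (l3 == l1).all()  # same images, same vote slots
        scores_a.extend(s3)
        scores_b.extend(s1)
        labels.extend(l3)
    z, p = correlated_auc_test(scores_a, scores_b, labels)
    assert z > 0
    assert p < 0.001


def exact_binomial_auc(k, p_pos, p_neg):
    """AUC of Binomial(k, p_pos)/k scores vs Binomial(k, p_neg)/k scores."""
    i = np.arange(k + 1)
    fp = stats.binom.pmf(i, k, p_pos)
    fn = stats.binom.pmf(i, k, p_neg)
    gt = np.tril(np.ones((k + 1, k + 1)), -1)  # pos count > neg count
    return float(fp @ gt @ fn + 0.5 * fp @ fn)


def test_exact_aggregation_gain_is_nondecreasing():
    aucs = [exact_binomial_auc(k, 0.75, 0.25) for k in range(1, 21)]
    assert all(b >= a - 1e-12 for a, b in zip(aucs, aucs[1:]))
    assert aucs[0] == pytest.approx(0.75)  # k=1 is the per-vote binary AUC


def test_auc_vs_k_matches_binomial_enumeration_oracle():
    cfg = replace(
        calibration_preset("0.03c", 1),
        p_correct={"normal": 0.75, "mild": 0.75, "severe": 0.75},
        pool_size=400,
    )
    manifest = build_manifest(200, 200, 0)
    ds = simulate_study(cfg, manifest, seed=23)
    curve = auc_vs_k(ds, n_resamples=60, seed=5)
    means = {k: m for k, m, _ in curve.points}
    for k in (1, 5, 10, 20):
        assert means[k] == pytest.approx(
            exact_binomial_auc(k, 0.75, 0.25), abs=0.03
        )
    assert means[20] > means[1]  # aggregation gain


def test_auc_vs_k_full_k_is_deterministic(simulated_dataset):
    curve = auc_vs_k(simulated_dataset, k_min=20, k_max=20, n_resamples=50, seed=1)
    (k, mean, sd), = curve.points
    scores, labels = scores_from_dataset(simulated_dataset, "per_image")
    assert (k, sd) == (20, 0.0)
    assert mean == pytest.approx(mw_auc(scores, labels), abs=1e-12)
    assert curve.peak_k == 20


def test_auc_vs_k_rises_then_flattens(simulated_dataset):
    curve = auc_vs_k(simulated_dataset, n_resamples=40, seed=2)
    means = [m for _, m, _ in curve.points]
    assert means[9] - means[0] > 0.05  # steep early rise
    assert abs(means[19] - means[9]) < 0.05  # flat tail
    with pytest.raises(ValueError):
        auc_vs_k(simulated_dataset, k_max=21)
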