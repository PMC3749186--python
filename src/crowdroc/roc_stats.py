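"""Nonparametric ROC statistics for crowd-grading studies.

The area under the ROC curve is estimated as the tie-corrected Mann-Whitney
statistic: the probability that a randomly chosen positive observation
outscores a randomly chosen negative one, with ties counted half,

    AUC = (#{s+ > s-} + 0.5 * #{s+ = s-}) / (n_pos * n_neg).

Two scoring modes are used throughout the package:

* ``per_classification`` — each individual vote is one binary-scored
  observation (score 1 for an "abnormal" response, 0 otherwise; label
  positive when the image's reference grade is abnormal).  For binary
  scores the Mann-Whitney statistic reduces exactly to
  (sensitivity + specificity)/2 — the single-operating-point rater AUC.
* ``per_image`` — each image is one observation scored by its vote
  fraction, the continuous score that makes the graders-subsampling curve
  meaningful.

Confidence intervals come from either the Hanley-McNeil exponential
approximation or the DeLong structural-components variance; correlated
curves over the same observations are compared with the DeLong paired
z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from crowdroc.study_data import Dataset

MODES = ("per_classification", "per_image")
CI_METHODS = ("hanley_mcneil", "delong")


@dataclass
class RocResult:
    """AUC point estimate with its 95% CI and provenance.

    ``mode`` records how scores were formed (per_classification /
    per_image); ``method`` which variance estimator produced the interval.
    The score and label vectors are retained so a result can be re-derived
    or fed to the paired comparison test.
    """

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    mode: str
    method: str
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC {self.auc} outside [0,1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI does not bracket the AUC point estimate")


@dataclass
class AucCurve:
    """Mean AUC as a function of the number of graders used per image.

    ``points`` rows are (k, mean_auc, sd_auc) over ``n_resamples``
    subsamples of k votes per image; ``peak_k`` is the smallest k attaining
    the maximal mean AUC.
    """

    points: list[tuple[int, float, float]]
    n_resamples: int
    peak_k: int


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iuf":
        return arr.astype(bool)
    mapping = {"positive": True, "negative": False, "+": True, "-": False}
    try:
        return np.array([mapping[str(x)] for x in arr])
    except KeyError as exc:
        raise ValueError(f"unrecognized label {exc.args[0]!r}") from exc


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative observation")
    return n_pos, n_neg


def mw_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Tie-corrected Mann-Whitney AUC.

    Computed from midranks: with R+ the rank sum of the positives in the
    pooled midranked sample, AUC = (R+ - n_pos(n_pos+1)/2) / (n_pos n_neg),
    identical to counting concordant pairs with ties at half weight.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_bool_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos, n_neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def binary_auc(sensitivity: float, specificity: float) -> float:
    """AUC of a single-operating-point binary rater: (sens + spec)/2.

    Exactly equals ``mw_auc`` on per-classification binary predictions whose
    empirical sensitivity and specificity are the given rates (the tie
    correction contributes the off-diagonal halves).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0,1]")
    return (sensitivity + specificity) / 2.0


def _structural_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong placements: per-positive and per-negative component vectors.

    V10[i] = fraction of negatives outscored by positive i (ties half);
    V01[j] = fraction of positives outscoring negative j (ties half).
    Both have mean equal to the AUC.
    """
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    m, n = len(pos), len(neg)
    pos_vals = scores[labels]
    neg_vals = scores[~labels]
    # counts below / at each positive among negatives, via binary search
    v10 = (
        np.searchsorted(neg, pos_vals, side="left")
        + 0.5 * (np.searchsorted(neg, pos_vals, side="right")
                 - np.searchsorted(neg, pos_vals, side="left"))
    ) / n
    v01 = (
        (m - np.searchsorted(pos, neg_vals, side="right"))
        + 0.5 * (np.searchsorted(pos, neg_vals, side="right")
                 - np.searchsorted(pos, neg_vals, side="left"))
    ) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def _hanley_mcneil_variance(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def auc_ci(
    scores: Sequence[float],
    labels: Sequence,
    method: str = "delong",
    mode: str = "per_classification",
    conf_level: float = 0.95,
) -> RocResult:
    """Mann-Whitney AUC with a normal-approximation CI, clipped to [0,1].

    ``method`` selects the variance estimator: ``hanley_mcneil`` (the
    classic exponential approximation with Q1 = A/(2-A), Q2 = 2A^2/(1+A))
    or ``delong`` (structural components; distribution-free and the natural
    companion of the paired comparison test).
    """
    if method not in CI_METHODS:
        raise ValueError(f"method must be one of {CI_METHODS}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    scores = np.asarray(scores, dtype=float)
    labels = _as_bool_labels(labels)
    n_pos, n_neg = _check_two_classes(labels)
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
    else:
        auc = mw_auc(scores, labels)
        var = _hanley_mcneil_variance(auc, n_pos, n_neg)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=n_pos,
        n_neg=n_neg,
        mode=mode,
        method=method,
        scores=scores,
        labels=labels,
    )


def correlated_auc_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence
) -> tuple[float, float]:
    """DeLong paired z test for two correlated ROC curves.

    Both score vectors must be over the same observations and labels.
    Returns (z, two-sided p) with
    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab); a zero-variance
    difference (e.g. identical scores) gives z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _as_bool_labels(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal lengths")
    _check_two_classes(labels)

    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)

    def _cov(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var_a = (np.var(v10_a, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01_a, ddof=1) / n if n > 1 else 0.0
    )
    var_b = (np.var(v10_b, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01_b, ddof=1) / n if n > 1 else 0.0
    )
    cov_ab = _cov(v10_a, v10_b) / m + _cov(v01_a, v01_b) / n
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 0.0:
        if abs(auc_a - auc_b) < 1e-12:
            return 0.0, 1.0
        raise ValueError("degenerate variance with unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def scores_from_dataset(
    dataset: Dataset, mode: str = "per_classification"
) -> tuple[np.ndarray, np.ndarray]:
    """Score/label vectors for ROC analysis of a dataset.

    ``per_classification``: one observation per vote, score 1 for an
    "abnormal" response; ``per_image``: one observation per image, score =
    vote fraction.  Labels are True where the reference grade is abnormal.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "per_classification":
        grade_map = dataset._grade_map
        scores = np.array(
            [1.0 if r.response == "abnormal" else 0.0 for r in dataset.records]
        )
        labels = np.array(
            [grade_map[r.image_id] != "normal" for r in dataset.records]
        )
        return scores, labels
    by_image = dataset.votes_by_image()
    scores_l: list[float] = []
    labels_l: list[bool] = []
    for im in dataset.manifest:
        votes = by_image[im.image_id]
        if not votes:
            continue
        scores_l.append(sum(v.response == "abnormal" for v in votes) / len(votes))
        labels_l.append(im.is_abnormal)
    return np.array(scores_l), np.array(labels_l)


def auc_vs_k(
    dataset: Dataset,
    k_min: int = 1,
    k_max: int | None = None,
    n_resamples: int = 200,
    seed: int = 0,
) -> AucCurve:
    """Per-image AUC as a function of the number of graders used.

    For each k in [k_min, k_max], repeatedly subsample k votes per image
    without replacement, score each image by its subsampled vote fraction,
    and compute the Mann-Whitney AUC against the binarized reference.
    At k equal to the full vote count the subsample is the full data, so a
    single deterministic evaluation is recorded with sd 0.  ``peak_k`` is
    the smallest k attaining the maximal mean AUC (cheapest design wins
    ties).
    """
    by_image = dataset.votes_by_image()
    images = [im for im in dataset.manifest if by_image[im.image_id]]
    if not images:
        raise ValueError("dataset has no votes")
    counts = {len(by_image[im.image_id]) for im in images}
    if len(counts) != 1:
        raise ValueError("auc_vs_k requires a complete dataset (equal votes/image)")
    k_full = counts.pop()
    if k_max is None:
        k_max = k_full
    if not (1 <= k_min <= k_max <= k_full):
        raise ValueError(
            f"need 1 <= k_min <= k_max <= {k_full}, got ({k_min}, {k_max})"
        )
    votes = np.array(
        [
            [v.response == "abnormal" for v in by_image[im.image_id]]
            for im in images
        ],
        dtype=float,
    )  # (n_images, k_full)
    labels = np.array([im.is_abnormal for im in images])
    rng = np.random.default_rng(seed)

    points: list[tuple[int, float, float]] = []
    for k in range(k_min, k_max + 1):
        if k == k_full:
            auc = mw_auc(votes.mean(axis=1), labels)
            points.append((k, auc, 0.0))
            continue
        aucs = np.empty(n_resamples)
        for r in range(n_resamples):
            # independent k-subset per image: first k of a random permutation
            order = np.argsort(rng.random(votes.shape), axis=1)[:, :k]
            fracs = np.take_along_axis(votes, order, axis=1).mean(axis=1)
            aucs[r] = mw_auc(fracs, labels)
        points.append((k, float(aucs.mean()), float(aucs.std(ddof=1))))
    best = max(points, key=lambda t: t[1])[1]
    peak_k = min(k for k, m, _ in points if m == best)
    return AucCurve(points=points, n_resamples=n_resamples, peak_k=peak_k)
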