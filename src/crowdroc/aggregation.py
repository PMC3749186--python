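"""Aggregate raw votes: vote fractions, strict-majority calls, stratified
sensitivity/specificity, and count-weighted pooled percentages.

Conventions
-----------
* The reference standard is binarized: mild and severe are both "abnormal".
* A vote is *correct* when it matches the binarized reference.
* The *strict majority* rule requires more than half of an image's votes to
  be correct; an exact 50/50 split is not a correct majority call.
* Printed percentages are rounded half-up to integer percent, which is the
  rule that reproduces the published pooled values from their strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from crowdroc.study_data import (
    ABNORMAL_GRADES,
    ClassificationRecord,
    Dataset,
    GRADES,
)

LEVELS = ("per_classification", "per_image_majority")


def round_half_up(x: float) -> int:
    """Round a nonnegative value half-up to the nearest integer."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Proportion:
    """A proportion carrying its integer counts."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"invalid proportion {self.numerator}/{self.denominator}"
            )

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> int:
        return round_half_up(100.0 * self.value)


@dataclass
class ConfusionSummary:
    """Stratified diagnostic accuracy at one level of analysis.

    ``sensitivity`` maps each abnormal stratum (mild, severe) present in the
    data to the proportion of its observations called abnormal;
    ``specificity`` is the proportion of normal-stratum observations called
    normal; ``pooled_sensitivity`` pools the abnormal strata by their counts.
    A stratum with no observations is simply absent (``None`` for
    specificity), never reported as 0/0.

    ``level`` is ``per_classification`` (each vote is one observation) or
    ``per_image_majority`` (each image is one observation, called by strict
    majority).
    """

    sensitivity: dict[str, Proportion]
    specificity: Optional[Proportion]
    pooled_sensitivity: Optional[Proportion]
    level: str


@dataclass
class MajorityResult:
    """Strict-majority analysis of every image.

    ``per_image`` rows are (image_id, vote_fraction, majority_correct);
    ``per_stratum`` maps each grade (plus the combined ``any_abnormal``
    stratum) to (percent of images majority-correct, (min, max) per-image
    percent of correct votes).
    """

    per_image: list[tuple[str, float, bool]]
    per_stratum: dict[str, tuple[float, tuple[float, float]]]


def _image_votes(dataset: Dataset, image_id: str) -> list[ClassificationRecord]:
    votes = [r for r in dataset.records if r.image_id == image_id]
    if not votes:
        raise ValueError(f"image {image_id!r} has no votes")
    return votes


def vote_fraction(dataset: Dataset, image_id: str) -> float:
    """Fraction of an image's votes that are 'abnormal' — the continuous
    per-image ROC score."""
    votes = _image_votes(dataset, image_id)
    return sum(v.response == "abnormal" for v in votes) / len(votes)


def majority_correct(dataset: Dataset, image_id: str) -> bool:
    """True iff strictly more than half of the votes match the binarized
    reference grade; an exact tie is False."""
    votes = _image_votes(dataset, image_id)
    grade = dataset.grade_of(image_id)
    correct_response = "abnormal" if grade in ABNORMAL_GRADES else "normal"
    n_correct = sum(v.response == correct_response for v in votes)
    return n_correct * 2 > len(votes)


def confusion_summary(dataset: Dataset, level: str = "per_classification") -> ConfusionSummary:
    """Stratified sensitivity/specificity.

    At ``per_classification`` level every vote is one observation.  At
    ``per_image_majority`` level every image is one observation whose call
    is its strict-majority vote.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    grade_map = dataset._grade_map

    correct: dict[str, int] = {g: 0 for g in GRADES}
    total: dict[str, int] = {g: 0 for g in GRADES}
    if level == "per_classification":
        for rec in dataset.records:
            g = grade_map[rec.image_id]
            expected = "abnormal" if g in ABNORMAL_GRADES else "normal"
            total[g] += 1
            correct[g] += rec.response == expected
    else:
        by_image = dataset.votes_by_image()
        for im in dataset.manifest:
            if not by_image[im.image_id]:
                continue
            total[im.grade] += 1
            correct[im.grade] += majority_correct(dataset, im.image_id)

    sensitivity = {
        g: Proportion(correct[g], total[g]) for g in ABNORMAL_GRADES if total[g] > 0
    }
    specificity = (
        Proportion(correct["normal"], total["normal"]) if total["normal"] > 0 else None
    )
    abn_num = sum(correct[g] for g in ABNORMAL_GRADES)
    abn_den = sum(total[g] for g in ABNORMAL_GRADES)
    pooled = Proportion(abn_num, abn_den) if abn_den > 0 else None
    return ConfusionSummary(
        sensitivity=sensitivity,
        specificity=specificity,
        pooled_sensitivity=pooled,
        level=level,
    )


def pooled_sensitivity_from_strata(
    strata: Sequence[tuple[float, int]]
) -> int:
    """Pool stratum sensitivities (percent, n classifications) into the
    count-weighted overall percent, rounded half-up.

    This reconstructs a published 'all abnormal' sensitivity from its
    per-stratum rows, e.g. [(61, 1200), (98, 200)] -> 66.
    """
    if not strata:
        raise ValueError("no strata given")
    num = 0.0
    den = 0
    for pct, n in strata:
        if n <= 0:
            raise ValueError(f"stratum size must be positive, got {n}")
        num += pct * n
        den += n
    return round_half_up(num / den)


def pooled_majority_from_strata(
    strata: Sequence[tuple[float, int]]
) -> int:
    """Pool per-stratum majority-correct percentages (percent, N images).

    Integer image counts are reconstructed per stratum by rounding half-up
    (c_i = round(pct_i/100 * N_i)) before pooling, because the underlying
    quantity is a count of images; e.g. [(58, 60), (100, 10)] -> 64.
    """
    if not strata:
        raise ValueError("no strata given")
    c = 0
    n = 0
    for pct, n_images in strata:
        if n_images <= 0:
            raise ValueError(f"stratum size must be positive, got {n_images}")
        c += round_half_up(pct / 100.0 * n_images)
        n += n_images
    return round_half_up(100.0 * c / n)


def majority_table(dataset: Dataset) -> MajorityResult:
    """Strict-majority summary per stratum, with per-image correct-vote ranges.

    For each grade (and the combined abnormal stratum) reports the percent of
    images whose strict majority matched the reference, and the min-max of
    the per-image percentage of correct votes.
    """
    by_image = dataset.votes_by_image()
    per_image: list[tuple[str, float, bool]] = []
    pct_correct: dict[str, list[float]] = {g: [] for g in GRADES}
    n_majority: dict[str, int] = {g: 0 for g in GRADES}
    n_images: dict[str, int] = {g: 0 for g in GRADES}

    for im in dataset.manifest:
        votes = by_image[im.image_id]
        if not votes:
            continue
        frac_abn = sum(v.response == "abnormal" for v in votes) / len(votes)
        correct_response = "abnormal" if im.is_abnormal else "normal"
        frac_correct = sum(v.response == correct_response for v in votes) / len(votes)
        maj = frac_correct * 2 > 1.0
        per_image.append((im.image_id, frac_abn, maj))
        g = im.grade
        n_images[g] += 1
        n_majority[g] += maj
        pct_correct[g].append(100.0 * frac_correct)

    per_stratum: dict[str, tuple[float, tuple[float, float]]] = {}
    for g in GRADES:
        if n_images[g] == 0:
            continue
        pcts = pct_correct[g]
        per_stratum[g] = (
            100.0 * n_majority[g] / n_images[g],
            (min(pcts), max(pcts)),
        )
    abn_imgs = sum(n_images[g] for g in ABNORMAL_GRADES)
    if abn_imgs > 0:
        abn_maj = sum(n_majority[g] for g in ABNORMAL_GRADES)
        abn_pcts = [p for g in ABNORMAL_GRADES for p in pct_correct[g]]
        per_stratum["any_abnormal"] = (
            100.0 * abn_maj / abn_imgs,
            (min(abn_pcts), max(abn_pcts)),
        )
    return MajorityResult(per_image=per_image, per_stratum=per_stratum)
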