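"""Synthetic crowd-grading datasets with the vote structure the analysis assumes.

The generator emulates a crowdsourced grading study: a pool of anonymous
workers, each image receiving K votes from K distinct workers, and per-vote
correct-classification probabilities stratified by reference grade (for
normal images the per-vote probability of a correct call is the per-vote
specificity; for mildly/severely abnormal images it is the per-vote
sensitivity).  Eight calibration presets — four study designs (reward and
eligibility tiers) in each of two repeat trials — carry the per-stratum
accuracies and worker-participation statistics reported for the original
crowdsourced retinal-grading study, so downstream aggregation and ROC
statistics can be exercised at realistic operating points without any
image data.

Worker heterogeneity is optional: per-worker ability offsets are drawn on
the log-odds scale with standard deviation 1/sqrt(heterogeneity_conc), so an
infinite concentration yields a homogeneous crowd whose aggregate proportions
match the configured accuracies exactly in expectation (the default, and the
calibration presets' setting).

One integer seed drives one named pseudo-random substream per concern
(worker profiles, assignment, responses, durations), so adding a concern
never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy.special import expit, logit

from crowdroc.study_data import (
    ClassificationRecord,
    Dataset,
    GRADES,
    ImageRecord,
    StudyDataError,
)

#: recognized design identifiers, in study-design order 1..4
PRESET_DESIGNS = ("0.03c", "0.05c", "0.03c_500_90", "0.03c_5000_99")
PRESET_TRIALS = (1, 2)

#: placeholder drop-down feature label attached to abnormal votes; stored,
#: never analyzed
ABNORMAL_FEATURE_LABEL = "abnormal_feature"


@dataclass(frozen=True)
class CrowdConfig:
    """One study design: reward, crowd size, per-vote accuracies, participation.

    Parameters
    ----------
    design_id, trial
        Label of the design and repeat-trial number.
    reward_usd
        Payment per classification, USD.
    graders_per_image
        K, the number of distinct workers voting on each image.
    p_correct
        Per-vote probability of a correct call by reference grade:
        ``{"normal": specificity, "mild": sens_mild, "severe": sens_severe}``.
    heterogeneity_conc
        Concentration of the worker-ability distribution.  Per-worker
        log-odds offsets are N(0, 1/heterogeneity_conc); ``math.inf``
        (default) means a homogeneous crowd.
    pool_size
        Number of distinct workers available.
    mean_hits_per_worker, sd_hits_per_worker
        Mean/SD of tasks per worker; sets the skew of the gamma-distributed
        activity weights used for worker-to-image assignment.
    duration_mean_secs, duration_sd_secs
        Mean/SD of the per-task duration; durations are log-normal with
        these moments.
    proportion_correct
        Printed "proportion correctly identified" metadata of the original
        study (a stricter, undefined correctness criterion); carried as
        preset metadata only, never used in simulation or analysis.
    """

    design_id: str
    trial: int = 1
    reward_usd: float = 0.03
    graders_per_image: int = 20
    p_correct: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.8, "mild": 0.7, "severe": 0.95}
    )
    heterogeneity_conc: float = math.inf
    pool_size: int = 100
    mean_hits_per_worker: float = 20.0
    sd_hits_per_worker: float = 20.0
    duration_mean_secs: float = 60.0
    duration_sd_secs: float = 60.0
    proportion_correct: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for g, p in self.p_correct.items():
            if g not in GRADES:
                raise ValueError(f"p_correct key {g!r} not a grade")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_correct[{g!r}]={p} outside [0,1]")
        if self.graders_per_image < 1:
            raise ValueError("graders_per_image must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.heterogeneity_conc <= 0:
            raise ValueError("heterogeneity_conc must be positive")


@dataclass(frozen=True)
class WorkerProfile:
    """A simulated worker: ability offset (log-odds) and activity weight."""

    worker_id: str
    ability_offset: float
    activity_weight: float

    def p_correct(self, base_p: float) -> float:
        """Per-vote correct probability for this worker given a stratum base rate."""
        if base_p <= 0.0 or base_p >= 1.0 or self.ability_offset == 0.0:
            return min(1.0, max(0.0, base_p))
        return float(expit(logit(base_p) + self.ability_offset))


# Calibration: per-vote accuracies from the published sensitivity (mild =
# difficult classification, severe = easy classification) and specificity
# (normal) for each design and trial; pool sizes, tasks-per-worker moments
# and per-task durations from the published participation table; the
# "proportion correctly identified" rows kept as metadata.
_PRESETS: dict[tuple[str, int], dict] = {
    ("0.03c", 1): dict(
        reward=0.03, p=dict(mild=0.61, severe=0.98, normal=0.74),
        pool=152, hits=(13.0, 18.0), dur=(78.0, 109.0),
        prop=dict(mild=0.57, normal=0.77, severe=0.96),
    ),
    ("0.05c", 1): dict(
        reward=0.05, p=dict(mild=0.70, severe=0.99, normal=0.68),
        pool=127, hits=(15.0, 20.0), dur=(62.0, 76.0),
        prop=dict(mild=0.64, normal=0.75, severe=0.92),
    ),
    ("0.03c_500_90", 1): dict(
        reward=0.03, p=dict(mild=0.61, severe=0.98, normal=0.85),
        pool=39, hits=(51.0, 96.0), dur=(63.0, 71.0),
        prop=dict(mild=0.55, normal=0.87, severe=0.90),
    ),
    ("0.03c_5000_99", 1): dict(
        reward=0.03, p=dict(mild=0.72, severe=0.99, normal=0.64),
        pool=61, hits=(26.0, 16.0), dur=(66.0, 90.0),
        prop=dict(mild=0.72, normal=0.64, severe=0.99),
    ),
    ("0.03c", 2): dict(
        reward=0.03, p=dict(mild=0.67, severe=0.99, normal=0.87),
        pool=69, hits=(37.0, 18.0), dur=(63.0, 83.0),
        prop=dict(mild=0.67, normal=0.87, severe=0.99),
    ),
    ("0.05c", 2): dict(
        reward=0.05, p=dict(mild=0.69, severe=0.96, normal=0.86),
        pool=72, hits=(35.0, 19.0), dur=(73.0, 105.0),
        prop=dict(mild=0.69, normal=0.86, severe=0.96),
    ),
    ("0.03c_500_90", 2): dict(
        reward=0.03, p=dict(mild=0.67, severe=0.98, normal=0.89),
        pool=56, hits=(25.0, 15.0), dur=(79.0, 102.0),
        prop=dict(mild=0.67, normal=0.89, severe=0.98),
    ),
    ("0.03c_5000_99", 2): dict(
        reward=0.03, p=dict(mild=0.79, severe=0.98, normal=0.52),
        pool=46, hits=(24.0, 14.0), dur=(58.0, 80.0),
        prop=dict(mild=0.79, normal=0.52, severe=0.98),
    ),
}


def calibration_preset(design_id: str, trial: int = 1) -> CrowdConfig:
    """Return the CrowdConfig calibrated to one published design/trial.

    ``design_id`` is one of ``0.03c``, ``0.05c``, ``0.03c_500_90``,
    ``0.03c_5000_99`` (study designs 1-4: reward per task and worker
    eligibility tier); ``trial`` is 1 or 2.  K is always 20 and workers are
    homogeneous, so the simulated aggregate proportions match the calibrated
    accuracies in expectation.
    """
    key = (design_id, trial)
    if key not in _PRESETS:
        raise ValueError(
            f"unknown preset {design_id!r} trial {trial}; valid design_ids are "
            f"{PRESET_DESIGNS} with trial in {PRESET_TRIALS}"
        )
    spec = _PRESETS[key]
    return CrowdConfig(
        design_id=design_id,
        trial=trial,
        reward_usd=spec["reward"],
        graders_per_image=20,
        p_correct=dict(spec["p"]),
        heterogeneity_conc=math.inf,
        pool_size=spec["pool"],
        mean_hits_per_worker=spec["hits"][0],
        sd_hits_per_worker=spec["hits"][1],
        duration_mean_secs=spec["dur"][0],
        duration_sd_secs=spec["dur"][1],
        proportion_correct=dict(spec["prop"]),
    )


def all_presets() -> list[CrowdConfig]:
    """All eight calibration presets, designs 1-4 within trial 1 then trial 2."""
    return [calibration_preset(d, t) for t in PRESET_TRIALS for d in PRESET_DESIGNS]


def build_manifest(
    n_normal: int, n_mild: int, n_severe: int
) -> list[ImageRecord]:
    """Deterministic manifest with the requested stratum composition.

    Ids are ``img_001``... in normal, mild, severe order.  The original
    study's composition is (30, 60, 10).
    """
    if min(n_normal, n_mild, n_severe) < 0:
        raise ValueError("stratum counts must be nonnegative")
    total = n_normal + n_mild + n_severe
    if total == 0:
        raise ValueError("empty study: all stratum counts are zero")
    width = max(3, len(str(total)))
    grades = ["normal"] * n_normal + ["mild"] * n_mild + ["severe"] * n_severe
    return [
        ImageRecord(image_id=f"img_{i + 1:0{width}d}", grade=g)
        for i, g in enumerate(grades)
    ]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams of one integer seed."""
    root = np.random.SeedSequence(seed)
    names = ("workers", "assignment", "responses", "durations")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _draw_workers(config: CrowdConfig, rng: np.random.Generator) -> list[WorkerProfile]:
    n = config.pool_size
    ids = [f"kw_{i + 1:04d}" for i in range(n)]
    if math.isinf(config.heterogeneity_conc):
        offsets = np.zeros(n)
    else:
        offsets = rng.normal(0.0, 1.0 / math.sqrt(config.heterogeneity_conc), size=n)
    # Gamma activity weights matched to the tasks-per-worker mean/SD, giving
    # the heavy-tailed participation seen in real crowds.
    m, s = config.mean_hits_per_worker, config.sd_hits_per_worker
    shape = (m / s) ** 2 if s > 0 else None
    if shape is None:
        weights = np.full(n, m)
    else:
        weights = rng.gamma(shape, m / shape, size=n)
        weights = np.maximum(weights, 1e-9)
    return [
        WorkerProfile(worker_id=w, ability_offset=float(o), activity_weight=float(a))
        for w, o, a in zip(ids, offsets, weights)
    ]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if mean <= 0:
        raise ValueError("duration mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_study(
    config: CrowdConfig, manifest: Sequence[ImageRecord], seed: int
) -> Dataset:
    """Simulate one complete study: K votes per image from K distinct workers.

    For each image, K distinct workers are sampled from the pool with
    probability proportional to their activity weight.  A vote on an image
    of grade g is correct (abnormal for mild/severe, normal for normal) with
    probability ``expit(logit(p_correct[g]) + worker_ability_offset)``.
    Durations are log-normal with the configured moments.  Identical
    (config, manifest, seed) gives a bit-identical dataset.
    """
    k = config.graders_per_image
    if config.pool_size < k:
        raise StudyDataError(
            f"pool_size {config.pool_size} cannot supply {k} distinct graders per image"
        )
    if not manifest:
        raise StudyDataError("empty manifest")
    streams = _streams(seed)
    workers = _draw_workers(config, streams["workers"])
    weights = np.array([w.activity_weight for w in workers])
    probs = weights / weights.sum()

    rng_assign = streams["assignment"]
    rng_resp = streams["responses"]
    rng_dur = streams["durations"]
    mu, sigma = _lognormal_params(config.duration_mean_secs, config.duration_sd_secs)

    records: list[ClassificationRecord] = []
    n_workers = len(workers)
    for image in manifest:
        chosen = rng_assign.choice(n_workers, size=k, replace=False, p=probs)
        base_p = config.p_correct[image.grade]
        correct_response = "abnormal" if image.is_abnormal else "normal"
        wrong_response = "normal" if image.is_abnormal else "abnormal"
        u = rng_resp.random(k)
        durations = rng_dur.lognormal(mu, sigma, size=k)
        for idx, ui, dur in zip(chosen, u, durations):
            w = workers[idx]
            p = w.p_correct(base_p)
            response = correct_response if ui < p else wrong_response
            records.append(
                ClassificationRecord(
                    worker_id=w.worker_id,
                    image_id=image.image_id,
                    response=response,
                    feature_label=(
                        ABNORMAL_FEATURE_LABEL if response == "abnormal" else ""
                    ),
                    duration_secs=round(float(dur), 3),
                    design_id=config.design_id,
                    trial=config.trial,
                )
            )
    return Dataset(manifest=list(manifest), records=records, design=config)


def study_cost(config: CrowdConfig, manifest: Sequence[ImageRecord]) -> float:
    """Total payout in USD: n_images x K x reward per classification."""
    return len(manifest) * config.graders_per_image * config.reward_usd


def config_from_yaml(
    path: Union[str, Path], base: Optional[CrowdConfig] = None
) -> CrowdConfig:
    """Load a CrowdConfig from YAML, overriding fields of ``base`` if given.

    Recognized keys are the CrowdConfig field names; ``heterogeneity_conc``
    accepts the strings ``inf``/``.inf`` for a homogeneous crowd.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"YAML config {path} must be a mapping")
    if "heterogeneity_conc" in raw and isinstance(raw["heterogeneity_conc"], str):
        raw["heterogeneity_conc"] = float(raw["heterogeneity_conc"])
    if base is None:
        if "design_id" not in raw:
            raise ValueError("YAML config without a base must set design_id")
        return CrowdConfig(**raw)
    return replace(base, **raw)
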