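"""Domain types, CSV I/O and validation for crowd-grading datasets.

A study consists of an image *manifest* (one row per image with its expert
reference grade) and a table of *classification records* (one row per vote:
worker, image, binary normal/abnormal response, optional feature label,
duration, study design and trial).  Because no raw per-vote data for the
original study is public, the column schema here is this package's own;
it is the dialect the synthetic generator writes and every downstream
operation reads.

Manifest CSV columns: ``image_id,grade``.
Classification CSV columns:
``worker_id,image_id,response,feature_label,duration_secs,design_id,trial``
(comma-separated, UTF-8, header row mandatory; empty feature_label allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence, Union

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from crowdroc.synthetic_crowd import CrowdConfig

GRADES = ("normal", "mild", "severe")
#: reference grades that binarize to "abnormal"
ABNORMAL_GRADES = ("mild", "severe")
RESPONSES = ("normal", "abnormal")

MANIFEST_COLUMNS = ["image_id", "grade"]
CLASSIFICATION_COLUMNS = [
    "worker_id",
    "image_id",
    "response",
    "feature_label",
    "duration_secs",
    "design_id",
    "trial",
]


class StudyDataError(ValueError):
    """Raised for malformed manifests or classification tables."""


@dataclass(frozen=True)
class ImageRecord:
    """One image of the reference standard: opaque id plus expert grade."""

    image_id: str
    grade: str  # one of GRADES

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise StudyDataError(
                f"unknown grade {self.grade!r} for image {self.image_id!r}; "
                f"expected one of {GRADES}"
            )

    @property
    def is_abnormal(self) -> bool:
        return self.grade in ABNORMAL_GRADES


@dataclass(frozen=True)
class ClassificationRecord:
    """One worker's vote on one image."""

    worker_id: str
    image_id: str
    response: str  # one of RESPONSES
    feature_label: str = ""
    duration_secs: float = 0.0
    design_id: str = ""
    trial: int = 1

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise StudyDataError(
                f"unknown response {self.response!r} on image {self.image_id!r}"
            )
        if self.duration_secs < 0:
            raise StudyDataError(
                f"negative duration {self.duration_secs} on image {self.image_id!r}"
            )
        if self.trial < 1:
            raise StudyDataError(f"trial must be >= 1, got {self.trial}")

    @property
    def key(self) -> tuple:
        """Uniqueness key: a worker may grade an image once per design/trial."""
        return (self.worker_id, self.image_id, self.design_id, self.trial)


@dataclass
class Dataset:
    """A manifest plus its classification records (and, optionally, the
    generating design configuration, when the dataset is simulated)."""

    manifest: list[ImageRecord]
    records: list[ClassificationRecord]
    design: Optional["CrowdConfig"] = None

    def grade_of(self, image_id: str) -> str:
        return self._grade_map[image_id]

    @property
    def _grade_map(self) -> dict[str, str]:
        cached = getattr(self, "_grade_map_cache", None)
        if cached is None or len(cached) != len(self.manifest):
            cached = {im.image_id: im.grade for im in self.manifest}
            object.__setattr__(self, "_grade_map_cache", cached)
        return cached

    def votes_by_image(self) -> dict[str, list[ClassificationRecord]]:
        out: dict[str, list[ClassificationRecord]] = {
            im.image_id: [] for im in self.manifest
        }
        for rec in self.records:
            out[rec.image_id].append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.worker_id,
                    r.image_id,
                    r.response,
                    r.feature_label,
                    r.duration_secs,
                    r.design_id,
                    r.trial,
                )
                for r in self.records
            ],
            columns=CLASSIFICATION_COLUMNS,
        )


@dataclass
class ValidationReport:
    """Counts and rule violations for a dataset; never raises."""

    n_images: int
    n_records: int
    n_workers: int
    records_per_image: dict[str, float]  # min / max / mean summary
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _normalize_grade(raw: str, row_label: str) -> str:
    g = str(raw).strip().lower()
    aliases = {
        "normal": "normal",
        "mild": "mild",
        "mildly abnormal": "mild",
        "severe": "severe",
        "severely abnormal": "severe",
    }
    if g not in aliases:
        raise StudyDataError(f"unknown grade value {raw!r} at {row_label}")
    return aliases[g]


def read_manifest(path: Union[str, Path]) -> list[ImageRecord]:
    """Read an image manifest CSV (``image_id,grade``).

    Grades are normalized case-insensitively to {normal, mild, severe}.
    Duplicate image ids or unknown grades are hard errors naming the row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise StudyDataError(f"manifest {path} missing columns {missing}")
    records: list[ImageRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        image_id = str(row.image_id)
        if image_id in seen:
            raise StudyDataError(f"duplicate image_id {image_id!r} at row {i + 2}")
        seen.add(image_id)
        grade = _normalize_grade(row.grade, f"row {i + 2} (image {image_id!r})")
        records.append(ImageRecord(image_id=image_id, grade=grade))
    return records


def write_manifest(manifest: Sequence[ImageRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(im.image_id, im.grade) for im in manifest], columns=MANIFEST_COLUMNS
    ).to_csv(path, index=False)


def read_classifications(
    path: Union[str, Path],
    manifest: Sequence[ImageRecord],
    design: Optional["CrowdConfig"] = None,
) -> Dataset:
    """Read a classification CSV against an already-loaded manifest.

    Input row order is preserved.  A vote on an image absent from the
    manifest, or a duplicate (worker, image, design, trial), is a hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLASSIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise StudyDataError(f"classification file {path} missing columns {missing}")
    known_ids = {im.image_id for im in manifest}
    records: list[ClassificationRecord] = []
    seen: set[tuple] = set()
    dupes: list[tuple] = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.image_id not in known_ids:
            raise StudyDataError(
                f"row {i + 2}: image_id {row.image_id!r} not in manifest"
            )
        rec = ClassificationRecord(
            worker_id=str(row.worker_id),
            image_id=str(row.image_id),
            response=str(row.response).strip().lower(),
            feature_label=str(row.feature_label),
            duration_secs=float(row.duration_secs),
            design_id=str(row.design_id),
            trial=int(row.trial),
        )
        if rec.key in seen:
            dupes.append(rec.key)
        seen.add(rec.key)
        records.append(rec)
    if dupes:
        raise StudyDataError(
            f"duplicate (worker, image, design, trial) classifications: {dupes}"
        )
    return Dataset(manifest=list(manifest), records=records, design=design)


def write_classifications(dataset: Dataset, path: Union[str, Path]) -> None:
    dataset.to_frame().to_csv(path, index=False)


def validate(dataset: Dataset) -> ValidationReport:
    """Enumerate invariant violations without raising.

    Checks: every record's image is in the manifest; no duplicate
    (worker, image, design, trial); nonnegative durations; and, when the
    dataset carries a design, exactly K records per image.
    """
    violations: list[tuple[str, str]] = []
    known_ids = {im.image_id for im in dataset.manifest}

    per_image: dict[str, int] = {iid: 0 for iid in known_ids}
    workers: set[str] = set()
    seen: set[tuple] = set()
    for rec in dataset.records:
        workers.add(rec.worker_id)
        if rec.image_id not in known_ids:
            violations.append(("unknown_image", rec.image_id))
        else:
            per_image[rec.image_id] += 1
        if rec.key in seen:
            violations.append(("duplicate_vote", str(rec.key)))
        seen.add(rec.key)
        if rec.duration_secs < 0:
            violations.append(("negative_duration", rec.image_id))

    counts = list(per_image.values())
    if dataset.design is not None:
        k = dataset.design.graders_per_image
        for iid in sorted(known_ids):
            if per_image[iid] != k:
                violations.append(("records_per_image", iid))

    summary = {
        "min": float(min(counts)) if counts else 0.0,
        "max": float(max(counts)) if counts else 0.0,
        "mean": float(sum(counts) / len(counts)) if counts else 0.0,
    }
    return ValidationReport(
        n_images=len(dataset.manifest),
        n_records=len(dataset.records),
        n_workers=len(workers),
        records_per_image=summary,
        violations=violations,
    )


def stratum_counts(dataset: Dataset) -> dict[str, tuple[int, int]]:
    """Per reference grade: (number of images, number of classifications)."""
    n_images = {g: 0 for g in GRADES}
    n_class = {g: 0 for g in GRADES}
    for im in dataset.manifest:
        n_images[im.grade] += 1
    grade_map = dataset._grade_map
    for rec in dataset.records:
        g = grade_map.get(rec.image_id)
        if g is not None:
            n_class[g] += 1
    return {g: (n_images[g], n_class[g]) for g in GRADES}
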