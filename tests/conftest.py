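import pytest

from crowdroc import build_manifest, calibration_preset, simulate_study
from crowdroc.study_data import ClassificationRecord, Dataset, ImageRecord


def toy_dataset(grades, votes, design=None):
    """Hand-build a dataset from {image_id: grade} and {image_id: [responses]}."""
    manifest = [ImageRecord(i, g) for i, g in grades.items()]
    records = [
        ClassificationRecord(worker_id=f"w{j:03d}", image_id=i, response=resp)
        for i, rs in votes.items()
        for j, resp in enumerate(rs)
    ]
    return Dataset(manifest=manifest, records=records, design=design)


@pytest.fixture(scope="session")
def paper_manifest():
    """The study composition: 30 normal, 60 mildly and 10 severely abnormal."""
    return build_manifest(30, 60, 10)


@pytest.fixture(scope="session")
def simulated_dataset(paper_manifest):
    """One complete simulated study (design 3, trial 1 calibration)."""
    return simulate_study(calibration_preset("0.03c_500_90", 1), paper_manifest, seed=7)
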