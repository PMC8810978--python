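import numpy as np
import pytest

from hclquant import (
    CircularROI,
    PatientRecord,
    PlanarImage,
    generate_cohort,
    reference_cohort,
)
from hclquant.reference import Diagnosis


@pytest.fixture(scope="session")
def ref_cohort() -> list[PatientRecord]:
    return reference_cohort()


@pytest.fixture(scope="session")
def default_cohort() -> list[PatientRecord]:
    """One seeded cohort at the default (study-condition) parameters."""
    return generate_cohort(seed=20260924)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_records(hcl_values, diseased) -> list[PatientRecord]:
    """Tiny cohort helper: parallel H/CL values and disease flags."""
    return [
        PatientRecord(
            patient_id=f"p{i}",
            visual_grade=0,
            hcl=float(h),
            diagnosis=Diagnosis.TTR_CA if d else Diagnosis.NONE,
        )
        for i, (h, d) in enumerate(zip(hcl_values, diseased))
    ]


@pytest.fixture()
def symmetric_image() -> PlanarImage:
    rng = np.random.default_rng(7)
    half = rng.poisson(30.0, size=(40, 30))
    counts = np.hstack([half, half[:, ::-1]])
    return PlanarImage(counts=counts)


@pytest.fixture()
def heart_roi() -> CircularROI:
    return CircularROI((20.0, 14.0), 6.0)
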