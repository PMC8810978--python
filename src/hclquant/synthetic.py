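"""Synthetic phantoms and patient cohorts.

Patient images from the derivation cohort are not available, so every
downstream stage is exercised on synthetic data with the same statistical
structure:

* **Phantoms** — anterior-projection thorax count images: a uniform
  soft-tissue background, vertical bone stripes (spine on the midline,
  one rib band per side, mirror-symmetric), and a circular cardiac disc
  whose expected count rate scales with the Perugini grade.  Every pixel
  is an independent Poisson draw, which is exact for a counting detector.
  The geometry is deliberately minimal: H/CL only consumes regional count
  totals, so nothing beyond region means matters downstream.

* **Cohorts** — one record per patient with a visual grade, an H/CL value
  drawn from a normal distribution truncated below at ``hcl_floor``
  (ratios of positive count totals cannot approach zero), and a final
  diagnosis.  Defaults reproduce the 170-patient study conditions:
  grade sizes (77, 19, 7, 67), per-grade H/CL means and SDs, and the
  empirical grade x diagnosis composition.

All generators are pure functions of ``(params, seed)``: one root
``numpy`` SeedSequence per call, spawned into independent child streams
per grade so sub-sampling is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import reference as ref
from .quant import GeometryError, PlanarImage, QuantError, roi_pixels, CircularROI
from .reference import Diagnosis

__all__ = [
    "PhantomParams",
    "CohortParams",
    "PatientRecord",
    "PHANTOM_RATIO_BY_GRADE",
    "generate_phantom",
    "expected_rate_map",
    "generate_cohort",
    "reference_cohort",
]

#: Expected disc-mean / background ratio per grade under default phantom
#: parameters; grade 0 has no cardiac excess, grades 1-3 follow the
#: reference cohort's per-grade H/CL means.
PHANTOM_RATIO_BY_GRADE = (1.0,) + ref.GRADE_HCL_MEAN[1:]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and count rates of the thorax phantom.

    Rates are expected counts per pixel. ``cardiac_rate`` of ``None``
    selects the grade-dependent default
    ``PHANTOM_RATIO_BY_GRADE[grade] * background_rate``.
    """

    image_shape: tuple[int, int] = (128, 128)
    background_rate: float = 50.0
    bone_rate: float = 60.0
    cardiac_rate: float | None = None
    heart_center: tuple[float, float] = (50.0, 40.0)
    heart_radius: float = 12.0
    midline_col: float = 63.5

    def validate(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise QuantError("image_shape must be positive")
        for name in ("background_rate", "bone_rate"):
            if getattr(self, name) < 0:
                raise QuantError(f"{name} must be nonnegative")
        if self.cardiac_rate is not None and self.cardiac_rate < 0:
            raise QuantError("cardiac_rate must be nonnegative")
        if self.heart_radius <= 0:
            raise QuantError("heart_radius must be positive")
        for roi in (self.heart_roi(), self.contralateral_roi()):
            rows, cols = roi_pixels(roi)
            if rows.size and (
                rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w
            ):
                raise GeometryError("heart disc or its mirror extends beyond the image")
        if abs(self.heart_center[1] - self.midline_col) <= self.heart_radius:
            raise GeometryError("midline must lie strictly between the two discs")

    def heart_roi(self) -> CircularROI:
        return CircularROI(self.heart_center, self.heart_radius)

    def contralateral_roi(self) -> CircularROI:
        row, col = self.heart_center
        return CircularROI((row, 2 * self.midline_col - col), self.heart_radius)

    def cardiac_rate_for_grade(self, grade: int) -> float:
        if self.cardiac_rate is not None:
            return self.cardiac_rate
        return PHANTOM_RATIO_BY_GRADE[grade] * self.background_rate


def _bone_mask(shape: tuple[int, int], midline_col: float) -> np.ndarray:
    """Spine stripe on the midline plus one rib band per side."""
    h, w = shape
    cols = np.arange(w, dtype=float)
    spine = np.abs(cols - midline_col) <= 3.5
    lateral_offset = 0.42 * w
    ribs = (np.abs(cols - (midline_col - lateral_offset)) <= 3.5) | (
        np.abs(cols - (midline_col + lateral_offset)) <= 3.5
    )
    return np.broadcast_to(spine | ribs, (h, w)).copy()


def expected_rate_map(grade: int, params: PhantomParams) -> np.ndarray:
    """Per-pixel Poisson mean of the phantom (the generator's ground truth)."""
    if grade not in ref.GRADES:
        raise QuantError(f"grade must be in {ref.GRADES}, got {grade}")
    params.validate()
    h, w = params.image_shape
    rates = np.full((h, w), float(params.background_rate))
    rates[_bone_mask(params.image_shape, params.midline_col)] += params.bone_rate
    rows, cols = roi_pixels(params.heart_roi())
    rates[rows, cols] += params.cardiac_rate_for_grade(grade) - params.background_rate
    return rates


def generate_phantom(
    grade: int, params: PhantomParams = PhantomParams(), seed: int = 0
) -> PlanarImage:
    """Draw one Poisson phantom image for a given Perugini grade."""
    rates = expected_rate_map(grade, params)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = rng.poisson(rates)
    return PlanarImage(counts=counts, projection="anterior", time_post_injection=3.0)


def _default_mix() -> tuple[tuple[float, float, float], ...]:
    mixes = []
    for g in ref.GRADES:
        n = ref.GRADE_N[g]
        c = ref.GRADE_DIAGNOSIS_COUNTS[g]
        mixes.append(
            (c[Diagnosis.TTR_CA] / n, c[Diagnosis.LC_CA] / n, c[Diagnosis.NONE] / n)
        )
    return tuple(mixes)


@dataclass(frozen=True)
class CohortParams:
    """Statistical structure of a synthetic cohort.

    ``diagnosis_mix_per_grade`` gives per-grade proportions of
    (TTR-CA, LC-CA, none); defaults are the empirical reference-cohort
    proportions so simulator and worked-example fixtures agree.
    """

    n_per_grade: tuple[int, int, int, int] = ref.GRADE_N
    hcl_mean_per_grade: tuple[float, ...] = ref.GRADE_HCL_MEAN
    hcl_sd_per_grade: tuple[float, ...] = ref.GRADE_HCL_SD
    diagnosis_mix_per_grade: tuple[tuple[float, float, float], ...] = field(
        default_factory=_default_mix
    )
    hcl_floor: float = 0.5

    def validate(self) -> None:
        if len(self.n_per_grade) != 4 or any(n < 0 for n in self.n_per_grade):
            raise QuantError("n_per_grade must be 4 nonnegative integers")
        if sum(self.n_per_grade) == 0:
            raise QuantError("empty cohort: all n_per_grade are zero")
        if any(sd < 0 for sd in self.hcl_sd_per_grade):
            raise QuantError("hcl_sd_per_grade must be nonnegative")
        if self.hcl_floor <= 0:
            raise QuantError("hcl_floor must be positive")
        for g, mix in enumerate(self.diagnosis_mix_per_grade):
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-6:
                raise QuantError(f"diagnosis mix for grade {g} must sum to 1")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: visual grade, H/CL value (optional), final diagnosis."""

    patient_id: str
    visual_grade: int
    hcl: float | None
    diagnosis: Diagnosis

    def __post_init__(self) -> None:
        if self.visual_grade not in ref.GRADES:
            raise QuantError(f"visual_grade must be in {ref.GRADES}")
        if self.hcl is not None and not self.hcl > 0:
            raise QuantError("hcl must be positive when set")


def _apportion(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n into integer label counts."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _truncated_normal_hcl(
    rng: np.random.Generator, n: int, mean: float, sd: float, floor: float
) -> np.ndarray:
    if sd == 0:
        if mean < floor:
            raise QuantError("degenerate H/CL mean lies below hcl_floor")
        return np.full(n, mean)
    a = (floor - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    params: CohortParams = CohortParams(), seed: int = 0
) -> list[PatientRecord]:
    """Simulate a cohort with exact per-grade sizes and diagnosis marginals.

    H/CL values are truncated-normal draws per grade; diagnosis label
    counts are apportioned deterministically from the grade's mix (exact
    marginals) and shuffled over the grade's records.
    """
    params.validate()
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(4)]
    records: list[PatientRecord] = []
    diag_order = (Diagnosis.TTR_CA, Diagnosis.LC_CA, Diagnosis.NONE)
    for g in ref.GRADES:
        n = params.n_per_grade[g]
        if n == 0:
            continue
        rng = streams[g]
        hcl = _truncated_normal_hcl(
            rng, n, params.hcl_mean_per_grade[g], params.hcl_sd_per_grade[g],
            params.hcl_floor,
        )
        label_counts = _apportion(n, params.diagnosis_mix_per_grade[g])
        labels = np.repeat(np.arange(3), label_counts)
        rng.shuffle(labels)
        for i in range(n):
            records.append(
                PatientRecord(
                    patient_id=f"g{g}-{i:04d}",
                    visual_grade=g,
                    hcl=float(hcl[i]),
                    diagnosis=diag_order[labels[i]],
                )
            )
    return records


def reference_cohort() -> list[PatientRecord]:
    """The deterministic 170-record grade x diagnosis skeleton.

    H/CL is unset on every record: patient-level values were never
    published, so this fixture supports grade-level evaluation only
    (e.g. the visual rule's sensitivity and specificity).
    """
    records = []
    for g in ref.GRADES:
        i = 0
        for diag, n in ref.GRADE_DIAGNOSIS_COUNTS[g].items():
            for _ in range(n):
                records.append(
                    PatientRecord(
                        patient_id=f"g{g}-{i:04d}",
                        visual_grade=g,
                        hcl=None,
                        diagnosis=diag,
                    )
                )
                i += 1
    return records
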