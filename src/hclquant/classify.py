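"""Diagnostic classification rules.

Three families of rules are implemented:

* the ASNC three-category reading, combining the Perugini visual grade
  with the H/CL ratio: *suggestive* of TTR-CA (grade >= 2 or
  H/CL >= 1.5), *inconclusive* (grade 1 or H/CL in [1.0, 1.5)), *not
  suggestive* (grade 0 or H/CL < 1).  The rule is a disjunction per
  category, resolved with precedence suggestive > inconclusive >
  not_suggestive, so any suggestive clause wins.  "Between 1 and 1.49"
  is read as the half-open interval [1.0, 1.5) at full precision, which
  leaves no undefined gap between 1.49 and 1.50.

* pure H/CL threshold rules, either two-category (suggestive iff
  H/CL >= cutoff) or three-category with an inconclusive band
  [lower, cutoff).

* grade-1 reclassification: equivocal (grade 1) patients are reassigned
  to the grade whose cohort H/CL interval they best match.  The default
  assigns the nearest grade mean (parameter free, monotone in H/CL); a
  standardized variant divides the distance by the grade's SD so wide
  grades attract more.  Ties break toward the lower grade (conservative:
  fewer false TTR-CA calls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from statistics import mean as _mean, stdev as _stdev

from . import reference as ref
from .quant import QuantError
from .synthetic import PatientRecord

__all__ = [
    "Category",
    "GradeStats",
    "GradeIntervals",
    "ThresholdRule",
    "classify_asnc",
    "classify_threshold",
    "fit_grade_intervals",
    "reclassify_grade1",
    "reference_grade_intervals",
]


class Category(str, Enum):
    """ASNC-style three-category outcome."""

    SUGGESTIVE = "suggestive"
    INCONCLUSIVE = "inconclusive"
    NOT_SUGGESTIVE = "not_suggestive"


@dataclass(frozen=True)
class GradeStats:
    """H/CL summary for one grade; ``sd`` is None when n < 2 (undefined)."""

    mean: float
    sd: float | None
    n: int


@dataclass(frozen=True)
class GradeIntervals:
    """Per-grade H/CL mean +/- SD intervals driving reclassification."""

    stats: dict[int, GradeStats]

    def __getitem__(self, grade: int) -> GradeStats:
        return self.stats[grade]

    @property
    def grades(self) -> list[int]:
        return sorted(self.stats)

    def to_json(self, path: str | Path) -> None:
        payload = {
            str(g): {"mean": s.mean, "sd": s.sd, "n": s.n}
            for g, s in sorted(self.stats.items())
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GradeIntervals":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                int(g): GradeStats(mean=v["mean"], sd=v["sd"], n=int(v["n"]))
                for g, v in payload.items()
            }
        )


def reference_grade_intervals() -> GradeIntervals:
    """Published per-grade H/CL mean +/- SD of the 170-patient cohort."""
    return GradeIntervals(
        {
            g: GradeStats(ref.GRADE_HCL_MEAN[g], ref.GRADE_HCL_SD[g], ref.GRADE_N[g])
            for g in ref.GRADES
        }
    )


def _check_grade(visual_grade: int) -> None:
    if visual_grade not in ref.GRADES:
        raise QuantError(f"visual grade must be in {ref.GRADES}, got {visual_grade}")


def classify_asnc(visual_grade: int, hcl: float) -> Category:
    """ASNC three-category reading from visual grade and H/CL ratio."""
    _check_grade(visual_grade)
    if not hcl > 0:
        raise QuantError("hcl must be positive")
    if visual_grade >= 2 or hcl >= 1.5:
        return Category.SUGGESTIVE
    if visual_grade == 1 or 1.0 <= hcl < 1.5:
        return Category.INCONCLUSIVE
    return Category.NOT_SUGGESTIVE


@dataclass(frozen=True)
class ThresholdRule:
    """Pure H/CL threshold rule.

    ``two_category``: suggestive iff hcl >= cutoff, else not suggestive.
    ``three_category``: additionally inconclusive on
    [inconclusive_floor, cutoff).
    """

    cutoff: float
    mode: str = "two_category"
    inconclusive_floor: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("two_category", "three_category"):
            raise QuantError("mode must be two_category or three_category")
        if self.mode == "three_category":
            if self.inconclusive_floor is None:
                raise QuantError("three_category rule needs inconclusive_floor")
            if not self.inconclusive_floor < self.cutoff:
                raise QuantError("inconclusive_floor must be below cutoff")


def classify_threshold(hcl: float, rule: ThresholdRule) -> Category:
    """Classify an H/CL value by a threshold rule."""
    if not hcl > 0:
        raise QuantError("hcl must be positive")
    if hcl >= rule.cutoff:
        return Category.SUGGESTIVE
    if rule.mode == "three_category" and hcl >= rule.inconclusive_floor:
        return Category.INCONCLUSIVE
    return Category.NOT_SUGGESTIVE


def fit_grade_intervals(records: list[PatientRecord]) -> GradeIntervals:
    """Per-grade arithmetic mean and sample SD (n-1 denominator) of H/CL.

    Grades absent from the input are absent from the result; a grade with
    a single record gets ``sd=None`` (undefined, not zero).
    """
    if not records:
        raise QuantError("cannot fit intervals on an empty cohort")
    by_grade: dict[int, list[float]] = {}
    for r in records:
        if r.hcl is None:
            raise QuantError(f"record {r.patient_id} has no hcl value")
        by_grade.setdefault(r.visual_grade, []).append(r.hcl)
    stats = {
        g: GradeStats(
            mean=_mean(vals),
            sd=_stdev(vals) if len(vals) >= 2 else None,
            n=len(vals),
        )
        for g, vals in by_grade.items()
    }
    return GradeIntervals(stats)


def reclassify_grade1(
    hcl: float, intervals: GradeIntervals, variant: str = "nearest_mean"
) -> int:
    """Reassign an equivocal (grade 1) H/CL value to a Perugini grade.

    ``nearest_mean`` minimizes |hcl - mean_g|; ``standardized`` minimizes
    |hcl - mean_g| / sd_g and requires defined, positive SDs.  Ties break
    toward the lower grade.
    """
    if variant not in ("nearest_mean", "standardized"):
        raise QuantError("variant must be nearest_mean or standardized")
    missing = [g for g in ref.GRADES if g not in intervals.stats]
    if missing:
        raise QuantError(f"intervals missing grade(s) {missing}")
    best_grade, best_dist = None, None
    for g in ref.GRADES:
        s = intervals[g]
        dist = abs(hcl - s.mean)
        if variant == "standardized":
            if s.sd is None or s.sd == 0:
                raise QuantError(f"standardized variant needs sd > 0 for grade {g}")
            dist /= s.sd
        if best_dist is None or dist < best_dist - 1e-12:
            best_grade, best_dist = g, dist
    return best_grade  # type: ignore[return-value]
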