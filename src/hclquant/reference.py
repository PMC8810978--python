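"""Reference cohort summary statistics for the 170-patient derivation study.

These constants are the published grade-level summaries of the cohort the
method was derived on: per-Perugini-grade H/CL means and standard
deviations, the grade x final-diagnosis contingency table, and the
category-level outcomes of the diagnostic rules. They serve two purposes:

* defaults for the synthetic cohort generator, so simulations reproduce
  the study conditions; and
* deterministic worked-example fixtures for grade-level evaluation
  (patient-level H/CL values were never published).
"""

from __future__ import annotations

from enum import Enum


class Diagnosis(str, Enum):
    """Final (gold-standard) diagnosis label."""

    TTR_CA = "TTR-CA"
    LC_CA = "LC-CA"
    NONE = "none"


#: Perugini grades, in order.
GRADES = (0, 1, 2, 3)

#: Number of patients per Perugini grade (total 170).
GRADE_N = (77, 19, 7, 67)

#: Per-grade H/CL arithmetic mean.
GRADE_HCL_MEAN = (0.98, 1.32, 1.54, 2.40)

#: Per-grade H/CL sample standard deviation.
GRADE_HCL_SD = (0.11, 0.40, 0.35, 0.76)

#: Grade x diagnosis contingency: counts of (TTR-CA, LC-CA, none) per grade.
GRADE_DIAGNOSIS_COUNTS: dict[int, dict[Diagnosis, int]] = {
    0: {Diagnosis.TTR_CA: 0, Diagnosis.LC_CA: 3, Diagnosis.NONE: 74},
    1: {Diagnosis.TTR_CA: 8, Diagnosis.LC_CA: 5, Diagnosis.NONE: 6},
    2: {Diagnosis.TTR_CA: 7, Diagnosis.LC_CA: 0, Diagnosis.NONE: 0},
    3: {Diagnosis.TTR_CA: 66, Diagnosis.LC_CA: 1, Diagnosis.NONE: 0},
}

#: Outcome of the three-category rule at cutoff 1.5 (grade-independent
#: H/CL bands plus visual grade, the ASNC reading): category -> counts of
#: (TTR-CA, LC-CA, none).  75 suggestive (2 LC-CA), 45 inconclusive,
#: 50 not suggestive (3 LC-CA).
ASNC_1P5_FLOW: dict[str, dict[Diagnosis, int]] = {
    "suggestive": {Diagnosis.TTR_CA: 73, Diagnosis.LC_CA: 2, Diagnosis.NONE: 0},
    "inconclusive": {Diagnosis.TTR_CA: 8, Diagnosis.LC_CA: 4, Diagnosis.NONE: 33},
    "not_suggestive": {Diagnosis.TTR_CA: 0, Diagnosis.LC_CA: 3, Diagnosis.NONE: 47},
}

#: Two-category rule at cutoff 1.3: confusion counts against TTR-CA.
#: 76 of 81 TTR-CA test positive; 4 previously inconclusive patients became
#: positive of which 1 was not TTR-CA, giving 3 false positives overall.
CUTOFF_1P3_CONFUSION = {"tp": 76, "fn": 5, "fp": 3, "tn": 86}

#: Number of patients left inconclusive by each quantitative reading.
INCONCLUSIVE_N = {"cutoff_1.5": 45, "cutoff_1.3": 41}

#: Total cohort size.
N_TOTAL = 170
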