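"""High-level pipeline steps shared by the CLI and scripted runs."""

from __future__ import annotations

import numpy as np

from .classify import (
    Category,
    GradeIntervals,
    classify_asnc,
    classify_threshold,
    fit_grade_intervals,
    reclassify_grade1,
)
from .config import RunConfig
from .performance import (
    DiagnosticPerformance,
    KWResult,
    NoFeasibleCutoffError,
    RocCurve,
    confusion,
    dunn_posthoc,
    kruskal_wallis,
    optimal_cutoff,
    roc_curve,
    sens_spec,
)
from .quant import QuantError
from .synthetic import PatientRecord

__all__ = ["classify_cohort", "evaluate_cohort", "EvaluationReport"]


def classify_cohort(
    records: list[PatientRecord], config: RunConfig
) -> tuple[list[Category], list[int | None], GradeIntervals]:
    """ASNC categories and grade-1 reclassification for every record.

    Grade intervals are fitted on the cohort itself (the derivation-study
    procedure); reclassified_grade is None for records not grade 1.
    """
    intervals = fit_grade_intervals(records)
    categories = [classify_asnc(r.visual_grade, r.hcl) for r in records]
    reclassified: list[int | None] = [
        reclassify_grade1(r.hcl, intervals, config.reclassification_variant)
        if r.visual_grade == 1
        else None
        for r in records
    ]
    return categories, reclassified, intervals


class EvaluationReport(dict):
    """Plain dict of evaluation artifacts keyed by section name."""


def _visual_categories(records: list[PatientRecord]) -> list[Category]:
    table = {
        0: Category.NOT_SUGGESTIVE,
        1: Category.INCONCLUSIVE,
        2: Category.SUGGESTIVE,
        3: Category.SUGGESTIVE,
    }
    return [table[r.visual_grade] for r in records]


def evaluate_cohort(records: list[PatientRecord], config: RunConfig) -> EvaluationReport:
    """Per-rule performance, reclassification flow, KW/post-hoc, ROC.

    Every record needs an H/CL value.  Returns an EvaluationReport with
    keys ``performance`` (rule name -> DiagnosticPerformance),
    ``inconclusive_n`` (rule name -> count), ``reclassification_flow``
    (new grade -> count over grade-1 records), ``kw`` (KWResult with
    post-hoc), ``roc`` (RocCurve) and ``optimal_cutoff``.
    """
    if any(r.hcl is None for r in records):
        raise QuantError("evaluation requires hcl on every record")
    performance: dict[str, DiagnosticPerformance] = {}
    inconclusive_n: dict[str, int] = {}

    visual = _visual_categories(records)
    performance["visual"] = sens_spec(confusion(records, visual))
    inconclusive_n["visual"] = sum(c is Category.INCONCLUSIVE for c in visual)

    if config.use_asnc:
        cats = [classify_asnc(r.visual_grade, r.hcl) for r in records]
        performance["asnc"] = sens_spec(confusion(records, cats))
        inconclusive_n["asnc"] = sum(c is Category.INCONCLUSIVE for c in cats)

    for rule_cfg in config.rules:
        rule = rule_cfg.to_rule()
        cats = [classify_threshold(r.hcl, rule) for r in records]
        performance[rule_cfg.name] = sens_spec(confusion(records, cats))
        inconclusive_n[rule_cfg.name] = sum(c is Category.INCONCLUSIVE for c in cats)

    intervals = fit_grade_intervals(records)
    flow = {g: 0 for g in (0, 1, 2, 3)}
    for r in records:
        if r.visual_grade == 1:
            flow[reclassify_grade1(r.hcl, intervals, config.reclassification_variant)] += 1

    groups = [
        np.array([r.hcl for r in records if r.visual_grade == g])
        for g in (0, 1, 2, 3)
    ]
    nonempty = [g for g in groups if len(g) > 0]
    kw = kruskal_wallis(nonempty)
    posthoc = dunn_posthoc(nonempty) if all(len(g) > 0 for g in groups) else None
    kw = KWResult(
        statistic=kw.statistic,
        p_value=kw.p_value,
        mean_rank_per_group=kw.mean_rank_per_group,
        group_sizes=kw.group_sizes,
        posthoc_p=posthoc,
    )

    roc = roc_curve(records)
    ref_spec = config.evaluation.reference_specificity
    if ref_spec is None:
        rule_15 = [
            classify_threshold(r.hcl, _two_cat(1.5)) for r in records
        ]
        ref_spec = sens_spec(confusion(records, rule_15)).specificity
    try:
        chosen = optimal_cutoff(roc, "max_sens_hold_spec", reference_spec=ref_spec)
    except NoFeasibleCutoffError:
        chosen = None
    roc = RocCurve(
        thresholds=roc.thresholds, sens_at=roc.sens_at, spec_at=roc.spec_at,
        chosen_cutoff=chosen, criterion=f"max_sens_hold_spec@{ref_spec:.1f}",
    )

    return EvaluationReport(
        performance=performance,
        inconclusive_n=inconclusive_n,
        reclassification_flow=flow,
        intervals=intervals,
        kw=kw,
        roc=roc,
        optimal_cutoff=chosen,
    )


def _two_cat(cutoff: float):
    from .classify import ThresholdRule

    return ThresholdRule(cutoff=cutoff, mode="two_category")
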