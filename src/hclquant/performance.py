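"""Diagnostic performance evaluation.

Rules are evaluated against the final diagnosis with TTR-CA as the
disease-positive class; LC-CA and non-CA patients count as
disease-negative.  By default an *inconclusive* reading counts as
test-negative — this is the convention under which the reference
cohort's printed percentages are algebraically reproducible (e.g. 76 of
81 TTR-CA positive at the 1.3 cutoff gives 93.8% sensitivity) — with an
option to exclude inconclusive records instead.

The ROC sweep uses "positive iff hcl >= t" over the sorted distinct
observed H/CL values plus infinite sentinels, so sensitivity is
nonincreasing and specificity nondecreasing in the threshold.

Group comparison of H/CL across Perugini grades uses the Kruskal-Wallis
rank test (midrank tie correction, chi-squared limit with k-1 degrees of
freedom) with Dunn's z post-hoc on the pooled midranks, Holm-adjusted by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import Category
from .quant import QuantError
from .reference import Diagnosis
from .synthetic import PatientRecord

__all__ = [
    "ConfusionTable",
    "DiagnosticPerformance",
    "RocCurve",
    "KWResult",
    "NoFeasibleCutoffError",
    "round_half_up",
    "confusion",
    "sens_spec",
    "roc_curve",
    "optimal_cutoff",
    "kruskal_wallis",
    "dunn_posthoc",
]


class NoFeasibleCutoffError(ValueError):
    """No ROC threshold satisfies the requested specificity."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from the floor (98.876 -> 99), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts for one rule against the TTR-CA diagnosis."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_definition: str = "suggestive"
    disease_definition: str = "TTR-CA"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity and specificity (percent, full precision) with the table."""

    sensitivity: float
    specificity: float
    table: ConfusionTable

    def rounded(self, ndigits: int = 0) -> tuple[float, float]:
        return (
            round_half_up(self.sensitivity, ndigits),
            round_half_up(self.specificity, ndigits),
        )


def confusion(
    records: list[PatientRecord],
    categories: list[Category],
    positive: frozenset[Category] | set[Category] = frozenset({Category.SUGGESTIVE}),
    exclude_inconclusive: bool = False,
) -> ConfusionTable:
    """Count tp/fp/tn/fn for per-record rule outcomes.

    ``positive`` names the categories counted as test-positive; all others
    are test-negative, unless ``exclude_inconclusive`` drops inconclusive
    records from the table entirely.
    """
    if len(records) != len(categories):
        raise QuantError("records and categories must align")
    tp = fp = tn = fn = 0
    for rec, cat in zip(records, categories):
        if exclude_inconclusive and cat is Category.INCONCLUSIVE:
            continue
        diseased = rec.diagnosis is Diagnosis.TTR_CA
        test_pos = cat in positive
        if diseased and test_pos:
            tp += 1
        elif diseased:
            fn += 1
        elif test_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(
        tp=tp, fp=fp, tn=tn, fn=fn,
        positive_definition=" or ".join(sorted(c.value for c in positive)),
    )


def sens_spec(table: ConfusionTable) -> DiagnosticPerformance:
    """Sensitivity = 100*tp/(tp+fn); specificity = 100*tn/(tn+fp)."""
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise QuantError("empty disease-positive or disease-negative margin")
    return DiagnosticPerformance(
        sensitivity=100.0 * table.tp / (table.tp + table.fn),
        specificity=100.0 * table.tn / (table.tn + table.fp),
        table=table,
    )


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep of "positive iff hcl >= threshold".

    ``thresholds`` are the sorted distinct observed values with -inf/+inf
    sentinels; ``sens_at``/``spec_at`` are percent arrays aligned to them.
    """

    thresholds: np.ndarray
    sens_at: np.ndarray
    spec_at: np.ndarray
    chosen_cutoff: float | None = None
    criterion: str = ""

    @property
    def auc(self) -> float:
        fpr = 1.0 - self.spec_at / 100.0
        tpr = self.sens_at / 100.0
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(tpr[order], fpr[order]))


def roc_curve(records: list[PatientRecord]) -> RocCurve:
    """ROC curve of H/CL against the TTR-CA diagnosis."""
    hcl = np.array([r.hcl for r in records], dtype=float)
    if np.any(np.isnan(hcl)):
        raise QuantError("every record needs an hcl value for ROC analysis")
    disease = np.array([r.diagnosis is Diagnosis.TTR_CA for r in records])
    n_pos, n_neg = int(disease.sum()), int((~disease).sum())
    if n_pos == 0 or n_neg == 0:
        raise QuantError("ROC needs at least one diseased and one non-diseased record")
    thresholds = np.concatenate(([-np.inf], np.unique(hcl), [np.inf]))
    # positive iff hcl >= t: count via binary search on each class's sorted values
    pos_sorted = np.sort(hcl[disease])
    neg_sorted = np.sort(hcl[~disease])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    return RocCurve(
        thresholds=thresholds,
        sens_at=100.0 * tp / n_pos,
        spec_at=100.0 * (n_neg - fp) / n_neg,
    )


def optimal_cutoff(
    roc: RocCurve,
    criterion: str = "max_sens_hold_spec",
    reference_spec: float | None = None,
) -> float:
    """Select an H/CL cutoff from an ROC curve.

    ``max_sens_hold_spec``: among finite thresholds with specificity >=
    ``reference_spec``, the one with maximal sensitivity (the smallest
    such threshold).  ``youden``: maximize sensitivity + specificity - 100,
    ties to the larger threshold.
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise QuantError("ROC curve has no finite thresholds")
    t = roc.thresholds[finite]
    sens = roc.sens_at[finite]
    spec = roc.spec_at[finite]
    if criterion == "max_sens_hold_spec":
        if reference_spec is None:
            raise QuantError("max_sens_hold_spec needs reference_spec")
        feasible = spec >= reference_spec
        if not feasible.any():
            raise NoFeasibleCutoffError(
                f"no threshold reaches specificity {reference_spec}"
            )
        best_sens = sens[feasible].max()
        candidates = t[feasible & (sens == best_sens)]
        return float(candidates.min())
    if criterion == "youden":
        j = sens + spec - 100.0
        return float(t[j == j.max()].max())
    raise QuantError(f"unknown criterion {criterion!r}")


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis outcome with per-group mean ranks and post-hoc matrix."""

    statistic: float
    p_value: float
    mean_rank_per_group: list[float]
    group_sizes: list[int]
    posthoc_p: np.ndarray | None = field(default=None, repr=False)


def _pooled_mean_ranks(groups: list[np.ndarray]) -> tuple[list[float], np.ndarray]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # midranks
    mean_ranks, start = [], 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + len(g)].mean()))
        start += len(g)
    return mean_ranks, ranks


def kruskal_wallis(hcl_by_grade: list[np.ndarray | list[float]]) -> KWResult:
    """Rank-based k-group comparison of H/CL distributions.

    Midrank tie correction; p-value from the chi-squared limit with
    (k - 1) degrees of freedom.  All-identical input gives H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in hcl_by_grade if len(g) > 0]
    if len(groups) < 2:
        raise QuantError("Kruskal-Wallis needs at least 2 nonempty groups")
    mean_ranks, _ = _pooled_mean_ranks(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, 1.0, mean_ranks, [len(g) for g in groups])
    stat, p = sps.kruskal(*groups)
    return KWResult(float(stat), float(p), mean_ranks, [len(g) for g in groups])


def dunn_posthoc(
    hcl_by_grade: list[np.ndarray | list[float]], adjust: str = "holm"
) -> np.ndarray:
    """Dunn's pairwise z-tests on pooled midranks.

    Returns the symmetric k x k matrix of two-sided p-values (NaN on the
    diagonal), adjusted by ``holm`` (default), ``bonferroni`` or ``none``.
    """
    groups = [np.asarray(g, dtype=float) for g in hcl_by_grade]
    if sum(len(g) > 0 for g in groups) < 2:
        raise QuantError("post-hoc needs at least 2 nonempty groups")
    if any(len(g) == 0 for g in groups):
        raise QuantError("post-hoc requires every group nonempty")
    if adjust not in ("holm", "bonferroni", "none"):
        raise QuantError(f"unknown adjustment {adjust!r}")
    mean_ranks, ranks = _pooled_mean_ranks(groups)
    n_total = len(ranks)
    # tie correction: sum(t^3 - t) over tied groups, as in Dunn (1964)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(groups)
    pmat = np.full((k, k), np.nan)
    pairs, raw = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            pairs.append((i, j))
            raw.append(min(p, 1.0))
    if adjust == "none":
        adjusted = raw
    else:
        adjusted = multipletests(raw, method=adjust)[1]
    for (i, j), p in zip(pairs, adjusted):
        pmat[i, j] = pmat[j, i] = float(p)
    return pmat
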