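"""Confusion/ROC/Kruskal-Wallis/Dunn against exhaustive brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hclquant import (
    Category,
    CohortParams,
    ConfusionTable,
    NoFeasibleCutoffError,
    QuantError,
    ThresholdRule,
    classify_threshold,
    confusion,
    dunn_posthoc,
    generate_cohort,
    kruskal_wallis,
    optimal_cutoff,
    roc_curve,
    round_half_up,
    sens_spec,
)
from hclquant.reference import Diagnosis
from hclquant.synthetic import PatientRecord

from conftest import make_records


def brute_force_confusion(records, categories, positive):
    tp = fp = tn = fn = 0
    for r, c in zip(records, categories):
        d = r.diagnosis is Diagnosis.TTR_CA
        p = c in positive
        tp += d and p
        fn += d and not p
        fp += (not d) and p
        tn += (not d) and not p
    return tp, fp, tn, fn


def brute_force_roc(records):
    """Evaluate every candidate threshold by direct counting."""
    hcl = [r.hcl for r in records]
    thresholds = [-math.inf] + sorted(set(hcl)) + [math.inf]
    out = []
    for t in thresholds:
        tp = sum(r.hcl >= t and r.diagnosis is Diagnosis.TTR_CA for r in records)
        fp = sum(r.hcl >= t and r.diagnosis is not Diagnosis.TTR_CA for r in records)
        npos = sum(r.diagnosis is Diagnosis.TTR_CA for r in records)
        nneg = len(records) - npos
        out.append((t, 100 * tp / npos, 100 * (nneg - fp) / nneg))
    return out


def brute_force_kw(groups):
    """Hand-ranked H statistic with midrank tie correction."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[k] = mid
        i = j
    rank_sums = [0.0] * len(groups)
    for idx, (_, gi) in enumerate(pooled):
        rank_sums[gi] += ranks[idx]
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    tie_counts = {}
    for v, _ in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in tie_counts.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


class TestConfusion:
    def test_visual_rule_on_reference_cohort(self, ref_cohort):
        cats = [
            Category.SUGGESTIVE if r.visual_grade >= 2 else Category.NOT_SUGGESTIVE
            for r in ref_cohort
        ]
        t = confusion(ref_cohort, cats)
        assert (t.tp, t.fn, t.fp, t.tn) == (73, 8, 1, 88)

    def test_all_positive(self, ref_cohort):
        cats = [Category.SUGGESTIVE] * len(ref_cohort)
        t = confusion(ref_cohort, cats)
        assert t.fn == 0 and t.tn == 0 and t.n == 170

    def test_exhaustive_six_record_combinations(self):
        records = make_records([1.0] * 6, [True, True, True, False, False, False])
        for combo in itertools.product(list(Category), repeat=6):
            t = confusion(records, list(combo))
            expected = brute_force_confusion(
                records, combo, {Category.SUGGESTIVE}
            )
            assert (t.tp, t.fp, t.tn, t.fn) == expected

    def test_exclude_inconclusive(self):
        records = make_records([1.0] * 4, [True, True, False, False])
        cats = [Category.SUGGESTIVE, Category.INCONCLUSIVE,
                Category.INCONCLUSIVE, Category.NOT_SUGGESTIVE]
        t = confusion(records, cats, exclude_inconclusive=True)
        assert t.n == 2 and (t.tp, t.tn) == (1, 1)

    def test_length_mismatch(self, ref_cohort):
        with pytest.raises(QuantError):
            confusion(ref_cohort, [Category.SUGGESTIVE])


class TestSensSpec:
    def test_visual_rule_percentages(self, ref_cohort):
        cats = [
            Category.SUGGESTIVE if r.visual_grade >= 2 else Category.NOT_SUGGESTIVE
            for r in ref_cohort
        ]
        perf = sens_spec(confusion(ref_cohort, cats))
        assert perf.rounded(0) == (90, 99)

    def test_perfect_table(self):
        perf = sens_spec(ConfusionTable(tp=1, fp=0, tn=1, fn=0))
        assert perf.sensitivity == 100.0 and perf.specificity == 100.0

    def test_one_decimal_sensitivity(self):
        perf = sens_spec(ConfusionTable(tp=76, fp=3, tn=86, fn=5))
        assert round_half_up(perf.sensitivity, 1) == 93.8
        assert round_half_up(perf.sensitivity, 0) == 94

    def test_empty_margin_rejected(self):
        with pytest.raises(QuantError):
            sens_spec(ConfusionTable(tp=0, fp=1, tn=1, fn=0))

    def test_round_half_up_not_bankers(self):
        assert round_half_up(98.876) == 99
        assert round_half_up(0.5) == 1
        assert round_half_up(1.25, 1) == 1.3


hcl_lists = st.lists(
    st.floats(0.5, 4.0).map(lambda x: round(x, 2)), min_size=2, max_size=20
)


class TestRoc:
    def test_perfect_separation_has_perfect_vertex(self):
        records = make_records(
            [0.8, 0.9, 1.0, 2.0, 2.2, 2.5], [False] * 3 + [True] * 3
        )
        roc = roc_curve(records)
        assert any(s == 100.0 and e == 100.0 for s, e in zip(roc.sens_at, roc.spec_at))

    def test_duplicate_values_collapse(self):
        records = make_records([1.0, 1.0, 2.0, 2.0], [False, False, True, True])
        roc = roc_curve(records)
        assert len(roc.thresholds) == 4  # -inf, 1.0, 2.0, +inf

    @given(data=st.data(), hcls=hcl_lists)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data, hcls):
        diseased = [data.draw(st.booleans()) for _ in hcls]
        if not (any(diseased) and not all(diseased)):
            diseased[0], diseased[-1] = True, False
        records = make_records(hcls, diseased)
        roc = roc_curve(records)
        oracle = brute_force_roc(records)
        assert len(roc.thresholds) == len(oracle)
        for (t, s, e), t2, s2, e2 in zip(
            oracle, roc.thresholds, roc.sens_at, roc.spec_at
        ):
            assert t == t2
            assert s == pytest.approx(s2)
            assert e == pytest.approx(e2)

    @given(data=st.data(), hcls=hcl_lists)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotonicity(self, data, hcls):
        diseased = [data.draw(st.booleans()) for _ in hcls]
        if not (any(diseased) and not all(diseased)):
            diseased[0], diseased[-1] = True, False
        roc = roc_curve(make_records(hcls, diseased))
        assert np.all(np.diff(roc.sens_at) <= 0)
        assert np.all(np.diff(roc.spec_at) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(QuantError):
            roc_curve(make_records([1.0, 2.0], [True, True]))


class TestOptimalCutoff:
    def test_lower_threshold_with_equal_specificity_wins(self):
        # negatives all below 1.3; positives straddle 1.3 and 1.5: both
        # thresholds have specificity 100 but 1.3 captures more positives
        records = make_records(
            [0.9, 1.0, 1.1, 1.3, 1.4, 1.5, 2.0],
            [False, False, False, True, True, True, True],
        )
        roc = roc_curve(records)
        assert optimal_cutoff(roc, "max_sens_hold_spec", reference_spec=100.0) == 1.3

    def test_single_threshold_curve(self):
        records = make_records([1.2, 1.2], [True, False])
        roc = roc_curve(records)
        assert optimal_cutoff(roc, "max_sens_hold_spec", reference_spec=0.0) == 1.2

    def test_youden_dominating_vertex(self):
        records = make_records(
            [1.0, 1.3, 1.2, 2.0, 2.1], [False, False, True, True, True]
        )
        roc = roc_curve(records)
        # J: 50 at t=1.2, 16.7 at t=1.3, 66.7 at t=2.0 (the dominating vertex)
        assert optimal_cutoff(roc, "youden") == 2.0

    def test_no_feasible_cutoff(self):
        records = make_records([1.0, 1.0], [True, False])
        roc = roc_curve(records)
        with pytest.raises(NoFeasibleCutoffError):
            optimal_cutoff(roc, "max_sens_hold_spec", reference_spec=101.0)


class TestKruskalWallis:
    def test_identical_groups_statistic_zero(self):
        result = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_hand_ranked_two_groups(self):
        result = kruskal_wallis([[1.0, 2.0], [3.0, 4.0]])
        assert result.statistic == pytest.approx(2.4)
        assert result.mean_rank_per_group == [1.5, 3.5]
        assert result.p_value == pytest.approx(sps.chi2.sf(2.4, 1))

    @given(
        groups=st.lists(
            st.lists(st.floats(0.5, 4.0).map(lambda x: round(x, 1)),
                     min_size=1, max_size=7),
            min_size=2, max_size=4,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, groups):
        if all(v == groups[0][0] for g in groups for v in g):
            groups[0] = groups[0] + [groups[0][0] + 1.0]
        result = kruskal_wallis(groups)
        assert result.statistic == pytest.approx(brute_force_kw(groups), abs=1e-9)

    @given(groups=st.lists(
        st.lists(st.floats(0.5, 4.0), min_size=2, max_size=6),
        min_size=3, max_size=4,
    ))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, groups):
        base = kruskal_wallis(groups)
        transformed = kruskal_wallis([[math.exp(v) for v in g] for g in groups])
        assert transformed.statistic == pytest.approx(base.statistic, abs=1e-8)

    def test_fewer_than_two_groups(self):
        with pytest.raises(QuantError):
            kruskal_wallis([[1.0, 2.0]])


class TestDunn:
    def test_identical_groups_p_near_one(self):
        p = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], adjust="none")
        assert p[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_z(self):
        groups = [[1.0, 1.2], [1.5, 1.7, 1.9], [2.5, 2.6]]
        p = dunn_posthoc(groups, adjust="none")
        # oracle: pooled midranks and Dunn z by direct arithmetic
        pooled = sorted(v for g in groups for v in g)
        rank = {v: pooled.index(v) + 1 for v in pooled}  # no ties here
        mean_ranks = [np.mean([rank[v] for v in g]) for g in groups]
        n = len(pooled)
        var = n * (n + 1) / 12.0
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(
                var * (1 / len(groups[i]) + 1 / len(groups[j]))
            )
            assert p[i, j] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_symmetry_and_diagonal(self):
        groups = [[1.0, 1.1], [1.5, 1.6], [2.0, 2.1], [3.0, 3.1]]
        p = dunn_posthoc(groups)
        assert np.allclose(p, p.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(p)))

    def test_holm_dominates_unadjusted(self):
        groups = [[1.0, 1.1, 1.2], [1.3, 1.4, 1.5], [2.0, 2.1, 2.2]]
        raw = dunn_posthoc(groups, adjust="none")
        holm = dunn_posthoc(groups, adjust="holm")
        mask = ~np.isnan(raw)
        assert np.all(holm[mask] >= raw[mask] - 1e-12)


class TestParameterRecovery:
    def test_cutoff_search_moves_below_1p5(self):
        """On large cohorts at the study's per-grade H/CL distributions,
        holding the 1.5-rule's specificity admits a lower cutoff."""
        successes = 0
        rule_15 = ThresholdRule(cutoff=1.5)
        for seed in range(10):
            params = CohortParams(n_per_grade=(7700, 1900, 700, 6700))
            records = generate_cohort(params, seed=seed)
            cats = [classify_threshold(r.hcl, rule_15) for r in records]
            ref_spec = sens_spec(confusion(records, cats)).specificity
            roc = roc_curve(records)
            try:
                cutoff = optimal_cutoff(
                    roc, "max_sens_hold_spec", reference_spec=ref_spec
                )
            except NoFeasibleCutoffError:
                continue
            if cutoff <= 1.5:
                successes += 1
        assert successes >= 9
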