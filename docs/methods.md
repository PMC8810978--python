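# Methods

## The quantification model

A planar scintigram is a grid of independent Poisson-distributed event
counts. The quantitative score is the heart/contralateral ratio: a
circular ROI is placed over the heart, copied, and mirrored across the
sternal midline; H/CL is the ratio of the two ROI count totals. No
background, blood-pool, decay or attenuation correction is applied — the
score is used exactly as acquired at 3 h post-injection in the anterior
projection (the library accepts other projections/times but warns, since
published cutoffs assume that acquisition).

Pixel membership is by the pixel-center rule (center within `radius`,
boundary inclusive), on 0-based `(row, col)` coordinates. The midline
must sit on an integer or half-integer column: reflection then maps
pixel centers to pixel centers, so the mirrored ROI contains exactly the
same number of pixels and the ratio compares equal-area regions. ROI
radius and placement are explicit inputs (readers of the original
protocol placed ROIs manually); `centroid_roi` optionally centers the
circle on the count-weighted centroid of a user-supplied search box. The
midline defaults to the image's central column, `(cols - 1) / 2`.

## Diagnostic rules

**ASNC three-category reading.** Suggestive of TTR-CA when grade ≥ 2 or
H/CL ≥ 1.5; inconclusive when grade 1 or H/CL ∈ [1.0, 1.5); not
suggestive when grade 0 or H/CL < 1. Each category is a disjunction, and
conflicts between the visual and quantitative clause are resolved by
precedence (suggestive > inconclusive > not suggestive): any suggestive
clause wins. The equivocal band is read as the half-open interval
[1.0, 1.5) at full precision rather than a two-decimal band ending at
1.49, which would leave (1.49, 1.50) undefined.

**Threshold rules.** Two-category (suggestive iff H/CL ≥ cutoff) or
three-category with an inconclusive band `[floor, cutoff)`; the
three-category 1.3 rule defaults to a [1.0, 1.3) band.

**Grade-1 reclassification.** Per-grade H/CL mean and sample SD (n − 1
denominator; SD undefined, not zero, for singleton grades) are fitted on
the cohort itself. An equivocal patient is reassigned to the grade
minimizing |H/CL − mean_g| — nearest-mean assignment. The per-grade
intervals overlap (grade 1's 1.32 ± 0.40 spans the grade-2 mean), so no
interval-membership rule can be total and unambiguous; nearest-mean is
parameter-free, monotone in H/CL, and reassigns low values to grade 0
and high values to grade 3 as the reference study describes. A
standardized variant minimizing |H/CL − mean_g| / sd_g is available
behind a flag for probing that ambiguity; both are interpretations,
since patient-level values that would disambiguate them were never
published. Ties break toward the lower grade (conservative: fewer false
TTR-CA calls).

## Performance evaluation

TTR-CA is the disease-positive class; LC-CA and non-CA are negative.
Inconclusive readings count as test-negative by default — the convention
under which the reference cohort's printed percentages are reproducible
from their own counts (76 of 81 → 93.8%) — with an option to exclude
them. Percentages are reported rounded half-up (98.876 → 99; banker's
rounding would print 98) to the nearest integer for table-style output,
one decimal elsewhere; full precision is kept internally.

The ROC sweep evaluates "positive iff H/CL ≥ t" over the sorted distinct
observed values plus ∓∞ sentinels. Cutoff optimization either holds a
reference specificity (returning the smallest threshold, hence largest
sensitivity, whose specificity is not below it) or maximizes Youden's
J = sens + spec − 100 with ties to the larger threshold. Only finite
thresholds are eligible; an unreachable reference specificity raises
`NoFeasibleCutoffError` rather than silently degrading.

Group comparison across grades uses the Kruskal–Wallis rank test
(scipy; midrank tie correction, χ² limit with k − 1 df) with per-group
mean ranks reported. The all-values-identical degenerate case is defined
as H = 0, p = 1. The post-hoc procedure is Dunn's z-test on the pooled
midranks with the 1964 tie correction, Holm-adjusted by default
(Bonferroni or unadjusted on request); the reference analysis names no
post-hoc method, and Dunn–Holm is the standard companion to
Kruskal–Wallis.

## Synthetic data

**Phantoms** emulate an anterior thorax projection: uniform soft-tissue
background, a spine stripe on the midline plus one rib band per side
(mirror-symmetric, so they cancel in expectation), and a circular
cardiac disc whose rate is `ratio_g × background_rate` with
`ratio_g = (1.0, 1.32, 1.54, 2.40)` per grade — grade 0 adds no cardiac
excess, grades 1–3 follow the reference per-grade H/CL means. Every
pixel is an independent Poisson draw. Defaults: 128×128 grid, 50
counts/pixel background (typical of a 3-h DPD planar acquisition),
+60 on bone, heart disc of radius 12 px centered at (50, 40), midline
at column 63.5. The geometry is deliberately minimal — no attenuation,
scatter, organ shapes or patient variability — because H/CL consumes
only regional count totals; passing phantom tests therefore validates
the counting and ratio arithmetic, not segmentation or realism.

**Cohorts** draw per-grade H/CL from a normal distribution truncated
below at `hcl_floor = 0.5` (the distribution family is not published;
truncation keeps ratios physical, and the reference SDs are small
relative to the means except at grade 1). Note the truncated mean
exceeds the configured mean by ≈0.02 at grade 1; tests that check
convergence use the truncated distribution's exact moments. Diagnosis
labels are apportioned deterministically from the grade's mix by largest
remainder — exact for the default empirical proportions, which makes the
simulated marginals (81/9/80) match the reference contingency exactly —
then shuffled across the grade's records. Randomness follows one root
seed spawned into one child stream per grade, so the same seed gives a
bit-identical cohort and marginals are seed-invariant.

`reference_cohort()` returns the deterministic 170-record grade ×
diagnosis skeleton with H/CL unset: patient-level values were never
published, so it supports grade-level evaluation only. Whether grade-1
TTR-CA and LC-CA patients differ in H/CL is unknowable from the
published summaries; the mix parameterization leaves that to the user.

## Problem sizes and numerical choices

Simulation-backed checks use cohorts of 170 (10 seeds) for the
Kruskal–Wallis property, 17,000 for cutoff recovery, and phantoms with
≥10⁵ expected disc counts (Poisson relative error ≈0.3%, asserted at
5%). Reclassification ties use a 10⁻¹² tolerance so floating-point noise
cannot flip the lower-grade tie-break. ROC counting is done by binary
search on the per-class sorted values (O(n log n)), and matches an
exhaustive per-threshold oracle exactly on small inputs.

## Known limitations

- The exact reference Kruskal–Wallis χ² (129.57), mean ranks, and the
  specific grade-1 patient reassignments require patient-level data that
  was never published; they are checked as distributional properties,
  not reproduced numerically.
- The reported 89% sensitivity at cutoff 1.5 is inconsistent with its
  own counts (73/81 = 90.1%); only internally consistent quantities are
  asserted.
- The phantom is not anatomically realistic and the cohort model treats
  H/CL within grade as unimodal; neither supports claims about scanner
  physics or reader variability.
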