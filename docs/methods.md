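# Methods

## Scoring model

Scoring operates on segment-level annotations: each lesion is a
(segment, maximal stenosis percent, composition) triple on the 18-segment
SCCT coronary model, with at most one lesion per segment (readers collapse
duplicate rows to the maximal stenosis and the worst composition, mixed >
non-calcified > calcified, before scoring). A lesion record implies plaque
is present; the >1 mm² cross-section criterion for calling a plaque is an
upstream reading decision, not re-checked here.

Severity grading uses the two published anchor definitions — obstructive
stenosis at ≥50% and severe plaque at strictly >70% — to fix the 0–3
grade scale: grade 1 below 50%, grade 2 from 50% to 70% inclusive, grade 3
above 70%. Grade 0 is reserved for "no plaque" and never returned for a
recorded lesion, which pins the stenosis coefficient SC to {0} ∪ [1, 3].
Whether the moderate stratum closes at 69% or 70% is not fixed by the
source definitions; 50–70 inclusive was chosen for consistency with the
strict ">70%" severe cut, and both cut points are configurable
(`GradeBoundaries`).

The CT-adapted Leaman score multiplies a dominance-dependent localization
weight by a composition factor (1.0 calcified, 1.5 non-calcified or mixed)
and a stenosis factor (1.0 obstructive, 0.615 non-obstructive). The weight
table is shipped as plain text and reproduced verbatim, including its six
"not applicable" cells (PDA under left dominance; PDA-from-LCA under right
and balanced; PL-from-LCA under right; PL-from-RCA under left and
balanced). One cell is anatomically debatable (PDA-from-LCA marked n/a
under balanced dominance while PL-from-LCA carries 0.5 there); the table
is reproduced as published rather than corrected. "n/a" cells are hard
errors, not zero weights: a lesion annotated on a segment that does not
exist under the patient's dominance indicates corrupt input, and a silent
zero would drop plaque burden. The applicable-weight sums (right 23.0,
left 23.0, balanced 22.5) are frozen as regression constants.

Two summation conventions are provided. `full_precision` (default) sums
exact per-lesion products. `paper_2dp` rounds each partial half-up to two
decimals before summing, matching the convention used when per-lesion
scores are reported to two decimals; on the packaged worked example it
gives 12.31 where exact arithmetic gives exactly 12.3. Rounding uses
decimal half-up, not binary banker's rounding, so 0.615 → 0.62.

## Eligibility and risk tiers

The diabetic arm follows ADA-style diagnosis (HbA1c ≥ 6.5%, FBG ≥ 7.0
mmol/L, 2-h post-challenge glucose ≥ 11.1 mmol/L, or current hypoglycemic
treatment), requires at least one of five cardiovascular risk factors
(hypertension ≥140/90 or treated; total cholesterol ≥ 5.2 mmol/L or
treated; current smoking; obesity BMI ≥ 28 kg/m² or lack of regular
exercise ≥3×/week, counted as one combined factor; family history of MI),
and excludes known/suspected CHD, abnormal resting ECG, prior
MI/CABG/stent and records with insufficient diagnostic data. A criterion
with missing inputs counts as not met and is reported by name, mirroring
the study practice of excluding incomplete records rather than imputing.

Risk tiers cut the UKPDS 10-year fatal-CHD risk percent at 7.5 and 15,
with both boundaries belonging to the moderate tier (low < 7.5 ≤ moderate
≤ 15 < high). The UKPDS risk engine itself is an external calculator; its
output is a required input column, and `stratify_record` accepts any
user-supplied risk function in its place.

## Statistics

Continuous scores are summarized as median (Q1, Q3) with linear
interpolation between closest ranks (any numpy quantile method is
selectable; the source reports no rule). Two-group comparisons use the
two-sided Mann–Whitney U test: for combined n ≤ 10 the p-value is exact by
full enumeration of rank assignments using midranks (tie-safe; the null
distribution of U remains symmetric about n₁n₂/2), otherwise the
tie-corrected normal approximation with continuity correction, which stays
within a few percent of the exact p at small n. Disabling the continuity
correction recovers the exact algebraic identity H = z² between the
two-group Kruskal–Wallis statistic and the squared standardized U.
Multi-group comparisons use Kruskal–Wallis with, post hoc, all
k(k−1)/2 pairwise tests multiplied by that count (Bonferroni, capped
at 1). Categorical comparisons use Pearson χ² without continuity
correction; expected counts below 5 trigger a warning rather than a
silent switch to an exact test.

Dichotomized findings (SIS > 3, SSS > 5, CT-LeSc > 8.7, obstructive
stenosis; strict inequalities, thresholds configurable) enter a binary
logistic regression with group indicators against the control reference.
Odds ratios are exponentiated ML coefficients with Wald 95% intervals; on
a single 2×2 table this reproduces the cross-product ratio ad/bc and the
closed-form Wald interval, which the tests verify independently. Complete
or quasi-complete separation (a group with constant outcome) is detected
up front and flagged, and no interval is reported for the affected
contrast.

One documented source inconsistency: the published χ² of 14.424 for the
severe-proximal-plaque contrast does not match Pearson χ² on the published
2×2 counts (≈9.07 by the hand formula n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)));
the variant behind the printed value is unstated. This package computes
Pearson and does not calibrate anything against that number.

## Synthetic cohort generator

The generator defines the study conditions for the tests: four groups of
74 / 40 / 48 / 53 patients (control and low / moderate / high risk
tiers). Per patient, dominance is drawn from a conventional anatomical
prior (0.85 right / 0.08 left / 0.07 balanced — the source states
dominance only for its worked example), then each anatomically applicable
segment independently receives a lesion with a group- and
segment-specific probability set to the published per-group segment count
divided by the group size (e.g. proximal LAD ≈ 0.50 in control, ≈ 0.91 in
the high tier), so expected lesion burden matches the published marginal
totals. Severity strata are mixed to reproduce the published obstructive
fractions (≈13 / 22 / 46 / 47% per group), with stenosis uniform at
10–49% (mild), 50–70% (moderate) and 71–95% (severe); composition mixes
use the published per-group calcified fractions (13 / 3 / 9 / 11%) with
the remainder split 24:76 between non-calcified and mixed. Covariates
(age, SBP, lipids, FBG, HbA1c, smoking, sex) are drawn from the per-group
published means/SDs; diabetes-duration medians (≈3 / 8 / 15 years across
tiers) are plausible defaults only, since the published per-tier
durations are typographically ambiguous. UKPDS risk is uniform within
each tier's band, so tier labels are consistent with stratification by
construction. Diabetic patients are emitted on hypoglycemic treatment
with at least one risk factor (hypertension is forced when no factor was
drawn — it is the most prevalent factor in this population at ~71%) and
no exclusion flags, so every generated diabetic record passes
eligibility.

Segments are independent within a patient; the source publishes no
within-patient correlation structure. An optional lognormal patient
frailty (`frailty_sd`) multiplies all segment probabilities to induce
clustering/overdispersion; it defaults to off. Consequences of the
simplifications: the generator reproduces configured marginals (verified
by parameter recovery within 3-sigma binomial bounds at 500
patients/group) and the qualitative tier ordering of all scores, but not
the published per-group medians, IQRs, test statistics or odds ratios,
which depend on unpublished patient-level data — green tests demonstrate
correctness of the pipeline under these conditions, not agreement with
any particular clinical cohort. Control patients in particular carry
fewer zero-lesion records than a real screening control group, because
independent Bernoulli draws rarely produce an empty tree at the
configured per-segment rates.

## Problem sizes and determinism

All randomness flows through a single `numpy` generator seeded from the
configuration, and a fixed seed yields byte-identical output tables. The
test suite uses 10⁴ random patients for the scoring-invariant sweep, 500
patients/group for parameter recovery and 200/group for the downstream
discrimination check — sizes at which the binomial recovery bounds are
tight and the whole suite runs in seconds. The acceptance script's anchor
quantities are deterministic worked-example values; its seed drives only
the end-to-end pipeline smoke run.

## Limitations

Segments are labels, not geometry: no vessel topology, centerlines,
calcium scoring or plaque volumetrics. The logistic models are
single-predictor group-indicator fits, not covariate-adjusted. The
control group is modelled as a convenience population, not a
propensity-matched one, and the Rose angina questionnaire stage of
asymptomatic-status ascertainment is out of scope.
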