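# coroscore

Coronary CT angiography (CCTA) plaque-burden scoring and coronary heart
disease (CHD) risk-tier cohort analysis, for radiologists and clinical
researchers who screen asymptomatic type 2 diabetes (T2DM) patients.

## What it computes

Lesions are annotated per segment on the 18-segment SCCT coronary model.
For each patient, five established plaque-burden scores are derived:

- **SIS** (segment involvement score): the number of segments with any
  plaque, `SIS = Σ_s 1[plaque in s]`, 0–18.
- **SSS** (segment stenosis score): each diseased segment is graded 1
  (mild, <50%), 2 (moderate, 50–70%), or 3 (severe, >70%) by maximal
  luminal diameter reduction, and the grades are summed.
- **SC** (stenosis coefficient): `SC = SSS / SIS` (0 when SIS = 0).
- **SPP** (severe proximal plaque): positive when any >70% stenosis sits
  in the left main or a proximal LAD/LCx/RCA segment.
- **CT-LeSc** (CT-adapted Leaman score): per lesion,
  `weight(segment, dominance) × c × k` with composition factor `c = 1`
  (calcified) or `1.5` (non-calcified or mixed) and stenosis factor
  `k = 1` (obstructive, ≥50%) or `0.615` (non-obstructive), summed over
  all lesions. Localization weights depend on coronary dominance and are
  shipped as an auditable table (`src/coroscore/data/ct_lesc_weights.csv`).

Around the scores the package provides: UKPDS 10-year fatal-CHD risk-tier
stratification of the diabetic arm (low < 7.5%, moderate 7.5–15%, high
> 15%; the risk engine's output percentage is an input, not reimplemented),
the group-comparison battery (Mann–Whitney U with exact small-sample
enumeration, Kruskal–Wallis with Bonferroni post-hoc, Pearson χ²,
group-indicator logistic odds ratios for SIS > 3, SSS > 5, CT-LeSc > 8.7
and obstructive stenosis), and a seeded synthetic cohort generator whose
defaults emulate the published four-group screening cohort
(74 control / 40 low / 48 moderate / 53 high).

## Worked example

The packaged fixture encodes a right-dominant patient with six mild
(<50%) lesions: mixed plaques in the left main, proximal LAD and mid LAD,
and calcified plaques in the 1st diagonal, proximal LCx and proximal RCA.

```python
from coroscore import load_worked_example, score_patient

panel = score_patient(load_worked_example(), rounding_mode="paper_2dp")
print(panel.partial_lesc)  # per-lesion CT-LeSc, 2-dp
print(panel.ct_lesc, panel.sis, panel.sss, panel.sc)
```

The per-lesion partials are `5 × 1.5 × 0.615 = 4.61` (left main),
`3.23` (proximal LAD), `2.31` (mid LAD), `0.62` (1st diagonal),
`0.92` (proximal LCx) and `0.62` (proximal RCA); they sum to a patient
CT-LeSc of **12.31**, with SIS 6, SSS 6, SC 1.0, SPP negative and no
obstructive lesion. The same run through the CLI:

```sh
$ coroscore score src/coroscore/data/worked_example_lesions.csv \
      -o scores.csv --rounding paper_2dp
$ cat scores.csv
patient_id,sis,sss,sc,spp,ct_lesc,has_obstructive
case01,6,6,1.0,False,12.31,False
```

## Cohort analysis

```python
from coroscore import CCTAScreeningAnalysis, default_config, generate_cohort

cohort = generate_cohort(default_config(seed=1))   # 215 synthetic patients
results = CCTAScreeningAnalysis(cohort).fit()
print(results.summary())
```

`fit()` scores every patient, compares the score distributions across
control / low / moderate / high groups (Kruskal–Wallis omnibus plus the
six Bonferroni-adjusted pairwise tests), tests the SPP ratio by χ², and
fits logistic odds ratios against the control group. On the default
synthetic cohort the moderate and high tiers show markedly higher median
SIS, SSS, SC and CT-LeSc than control (omnibus p ≪ 0.001) and elevated
odds of every dichotomized finding — the qualitative pattern the scoring
system is designed to surface. The CLI equivalents are
`coroscore simulate`, `coroscore stratify` and `coroscore compare`.

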