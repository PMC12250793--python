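# pedmets

Screening-index analysis for metabolic syndrome (MetS) in children and
adolescents, aimed at high-adiposity pediatric populations such as
Prader–Willi syndrome (PWS).

Clinicians screening pediatric cohorts for MetS would like a single, cheap
index — ideally one computable from a routine lipid panel — instead of the
full component workup (waist percentiles, blood pressure, fasting
biochemistry, DXA body composition). `pedmets` provides the machinery for
answering "which index screens best" quantitatively:

- **Indices** — BMI, BMI-SDS, tri-ponderal mass index (TMI, kg/m³),
  fat-mass and fat-free-mass indices (FMI/FFMI), body-mass-fat index
  (BMFI), a body shape index (ABSI), visceral adiposity index (VAI),
  waist-to-height ratio (WtHR), cardiometabolic index (CMI = WtHR ×
  TG/HDL-C), TC/HDL-C and TG/HDL-C ratios, plus HOMA-IR — with explicit,
  documented unit conventions (see `docs/methods.md`).
- **Diagnosis** — an age-dispatched MetS rule engine: IDEFICS-style
  percentile criteria for ages 7–<10 (≥3 of 4 components), IDF criteria
  for 10–<16 and ≥16 (mandatory abdominal-obesity gate plus ≥2 factors),
  with strict thresholds and treatment overrides in the adult-style band.
- **Evaluation** — ROC operating points, rank-based AUC with DeLong 95%
  CIs and paired AUC comparison, Youden-optimal cutoffs (J = sens + spec −
  1, ties toward the lower threshold), sensitivity/specificity/PPV/NPV and
  likelihood ratios with Wald or Clopper–Pearson intervals, Spearman
  correlations, rank-sum and chi-square tests, Lilliefors normality,
  box-plot outlier screening, and age/sex-resolved cutoff trends.
- **Synthetic cohorts** — a generative model (log-normal biochemistry, a
  single latent risk state shifting all MetS components jointly,
  general-population fixture percentile tables) that emulates a
  124-subject PWS-like cohort with ~19% MetS prevalence, so every stage is
  testable end to end without patient data.

## Worked example

```python
from pedmets import (CohortParams, simulate_cohort, make_reference_tables,
                     ScoredCohort, evaluate_index)
from pedmets.pipeline import index_frame, classify_frame

params = CohortParams(seed=1)                      # 124 subjects, ages 7-18
bmi_ref, provider = make_reference_tables(0, params)
cohort = simulate_cohort(params)
panels = index_frame(cohort, bmi_ref)              # 12 indices + HOMA-IR
classified = classify_frame(cohort, panels, provider)
labels = classified["mets"].astype(bool).to_numpy()

print(f"MetS prevalence: {labels.sum()}/124 ({100*labels.mean():.1f}%)")
for name in ("tg_hdl", "cmi", "bmi"):
    rep = evaluate_index(ScoredCohort(panels[name].to_numpy(), labels), index=name)
    m = rep.metrics
    print(f"{name:7s} AUC {rep.auc.value:.3f} ({rep.auc.lo:.3f}-{rep.auc.hi:.3f})  "
          f"cutoff {rep.cutoff:.2f}  J {rep.youden:.3f}  "
          f"sens {m['sens'].value:.3f}  spec {m['spec'].value:.3f}")
```

Output:

```
MetS prevalence: 28/124 (22.6%)
tg_hdl  AUC 0.866 (0.790-0.943)  cutoff 2.63  J 0.699  sens 0.929  spec 0.771
cmi     AUC 0.874 (0.801-0.946)  cutoff 1.65  J 0.741  sens 0.929  spec 0.812
bmi     AUC 0.584 (0.463-0.704)  cutoff 30.52  J 0.201  sens 0.357  spec 0.844
```

Read: in this simulated cohort 28 of 124 subjects meet MetS criteria. The
TG/HDL-C ratio and CMI are strong discriminators (AUC ≈ 0.87) with
Youden-optimal cutoffs of 2.63 and 1.65 respectively, while BMI alone is
barely better than chance (AUC 0.58) — the expected behaviour under the
generator's lipid-dominant risk structure, and the pattern reported for
real PWS cohorts.

## Command line

```bash
pedmets simulate --n 124 --seed 0 --out cohort.csv --references-out refs.csv
pedmets compute-indices --cohort cohort.csv --references refs.csv --out indices.csv
pedmets classify --cohort cohort.csv --references refs.csv --out classified.csv
pedmets evaluate --cohort cohort.csv --references refs.csv --index tg_hdl \
    --by-sex --out report.json --roc-out roc.csv
pedmets run --config config.yaml     # full pipeline with manifest
```

Exit codes: 0 success, 2 schema/validation error, 3 degenerate analysis.

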