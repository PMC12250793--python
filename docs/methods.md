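# Methods

## Scope

`pedmets` implements a complete screening-index analysis for metabolic
syndrome (MetS) in children and adolescents, aimed at high-adiposity
populations such as Prader–Willi syndrome (PWS). It has four layers:

1. **Indices** — twelve anthropometric/body-composition/lipid indices plus
   HOMA-IR per subject.
2. **Rule engine** — age-dispatched MetS diagnosis (IDEFICS-style below 10
   years, IDF-style above).
3. **Diagnostics** — ROC/AUC/Youden machinery and the supporting tests.
4. **Synthetic cohort** — a generative model with a known latent risk
   structure, so the full pipeline can be validated without patient data.

## Index definitions and unit conventions

All inputs are in clinical units: weight kg, height and waist cm, lipids
mg/dL, glucose mg/dL, insulin µU/mL, blood pressure mmHg.

| Index | Definition | Units/scale |
|---|---|---|
| BMI | weight / height² | kg/m² |
| BMI-SDS | z-score vs. age/sex reference | — |
| TMI | weight / height³ | kg/m³ |
| FMI / FFMI | DXA fat (fat-free) mass / height² | kg/m² |
| BMFI | BMI × fat-mass fraction × waist (m) | ~10 |
| ABSI | waist (m) / (BMI^⅔ · height (m)^½) | ~0.08 |
| VAI | sex-specific composite (below) | ~1 |
| WtHR | waist / height | ~0.5–0.7 |
| CMI | WtHR × TG/HDL-C | ~1 |
| TC/HDL-C, TG/HDL-C | ratios of mg/dL values | ~1–4 |
| HOMA-IR | glucose · insulin / 405 | ~1–4 |

Three conventions deserve comment because the composite indices are often
printed ambiguously in the clinical literature:

- **VAI.** The original sex-specific definition is used: males
  `WC/(39.68 + 1.88·BMI) · (TG/1.03) · (1.31/HDL)`, females
  `WC/(36.58 + 1.89·BMI) · (TG/0.81) · (1.52/HDL)`, lipids in mmol/L
  (TG mg/dL ÷ 88.57, cholesterol ÷ 38.67). A mis-parenthesised variant that
  circulates in print (`WC/39.68 + 1.88·BMI`) inflates the index by two
  orders of magnitude; it is available behind
  `literal_parenthesisation=True` strictly for sensitivity analysis.
- **BMFI.** Fat mass enters as a *fraction* and waist in *metres*; passing
  a percentage is rejected as a domain error. This keeps the index on the
  ~10 scale reported for pediatric cohorts.
- **ABSI.** Waist and height in metres, giving the conventional ~0.08
  scale.

**BMI-SDS reference contract.** A reference maps (sex, age) to (L, M, S).
When the skewness parameter L is absent or exactly 1, the reference is
treated as a plain normal with *absolute* SD `S`: z = (BMI − M)/S. For any
other L the Box–Cox (LMS) transform is applied with `S` as a coefficient of
variation: z = ((BMI/M)^L − 1)/(L·S), with the log form at L = 0. The dual
convention reflects how such tables are published (mean/SD tables vs. LMS
growth references); the shipped synthetic reference uses L = 1.

Missing DXA masses leave FMI/FFMI/BMFI *undefined* (never zero); analyses
drop undefined values listwise and report the counts.

## MetS rule engine

Age bands are half-open: [7, 10) IDEFICS, [10, 16) IDF with a percentile
waist gate, [16, ∞) IDF with absolute waist cuts. Every comparison is
strict, so a value exactly at a threshold is non-pathological, and a BMI-SDS
of exactly 2.0 is classified non-obese.

- **IDEFICS (7–<10 y):** four components — waist > p90; SBP or DBP > p90;
  TG > p90 or HDL < p10; HOMA-IR > p90 or glucose > p90 — at least three
  required. Percentiles come from an injected age/sex reference provider,
  linearly interpolated between half-year knots; a query outside the
  tabulated range is a coverage error, never a clamp.
- **IDF 10–<16 y:** mandatory waist > p90, plus ≥2 of TG > 150 mg/dL,
  HDL < 40 mg/dL, SBP > 130 or DBP > 85 mmHg, glucose > 100 mg/dL or
  diagnosed IGT/T2DM.
- **IDF ≥16 y:** waist gate > 94 cm (M) / > 80 cm (F); HDL cut 40 (M) /
  50 (F) mg/dL; lipid and BP treatment substitute for their factors.

Two genuinely open design points are resolved as follows. A previously
diagnosed IGT/T2DM counts as the glucose factor at *every* age (the
dysglycemia criterion is the one that applies to all ages); lipid/BP
treatment overrides apply only in the ≥16 band. A treated subject with
normal measured lipids contributes exactly **one** lipid factor; counting
treatment as both the TG and the HDL factor is available via
`treated_lipids_double_count=True`.

## Diagnostic statistics

- **Positivity convention:** score ≥ threshold is test-positive (high index
  = at risk) everywhere.
- **ROC / AUC:** one operating point per distinct score plus the trivial
  endpoints. AUC is the midrank Mann–Whitney concordance probability; its
  95% CI uses the DeLong structural-component variance. A single-member
  class contributes zero variance rather than NaN.
- **Youden cutoff:** exhaustive scan over observed scores maximising
  J = sens + spec − 1; ties (including float-noise ties, tolerance 1e−12)
  break toward the *lower* threshold — the higher-sensitivity screening
  choice.
- **Paired AUC comparison:** DeLong's test on the joint structural
  components; a permutation test serves as the cross-check in the test
  suite, never as the implementation.
- **Confusion metrics:** sens/spec/PPV/NPV with Wald intervals by default
  (clipped to [0, 1]); Clopper–Pearson optional. Likelihood-ratio CIs use
  the log method. Zero-margin metrics are explicitly `None`.
- **2×2 chi-square:** the continuity correction is a *required* argument
  ('none' | 'yates'); published 2×2 p-values cannot be reproduced without
  knowing the convention, so there is no silent default.
- **Rank tests:** Wilcoxon rank-sum uses exact enumeration when the pooled
  sample is ≤12 and tie-free, otherwise the tie-corrected normal
  approximation (scipy). Spearman correlation is the midrank Pearson
  correlation with the t-approximation p (scipy).
- **Normality:** one-sample KS against a moment-fitted normal with the
  Lilliefors correction (statsmodels simulated tables); the naive KS p is
  available for comparison.
- **Outliers:** Tukey box-plot fences (1.5·IQR beyond the quartiles);
  outliers are *reported, never removed*.
- **Age-specific cutoffs:** the age trend of an index cutoff is rebuilt by
  recomputing the Youden threshold inside a ±2-year sliding window per sex
  (defaults: window 4 y, min 10 subjects); windows that are too small or
  single-class yield explicit undefined points. This sliding-window
  construction is a documented approximation — there is no canonical
  estimator for an age-resolved cutoff curve.

## Synthetic cohort model

The generator emulates a 124-subject pediatric PWS-like cohort (ages 7–18,
~49% female, median BMI-SDS ≈ 2.1, ~52% obese, short stature for age) with
a **single latent Bernoulli risk state** (default probability 0.46) that
shifts all MetS components jointly: multiplicatively on TG (×e^0.65), HDL
(×e^−0.33), insulin, glucose and HbA1c, additively on waist (+2.5 cm), SBP
(+6), DBP (+7) and BMI-SDS (+0.55). Continuous biochemistry is log-normal;
BMI is drawn as a z-score and inverted through the shipped BMI reference,
so recomputed BMI-SDS recovers the generative z-score; weight follows from
BMI and height; DXA masses split weight by a sex-specific fat fraction
(higher in girls, as is dimorphism in height and glycemia — the only
dimorphic channels). Correlation between components arises *only* through
the shared risk state, which keeps the model analyzable.

Effect sizes were fixed so the risk-state marginals land on the scale
reported for MetS-positive pediatric PWS subjects (TG ≈ 135, HDL ≈ 39,
glucose ≈ 86 mg/dL, SBP ≈ 115, DBP ≈ 75 mmHg); the latent risk probability
was then calibrated once, by simulation, so the median realized MetS
prevalence at n = 124 is ≈ 19.4%, with higher prevalence among the obese.
The defaults are lipid-dominant by design: the analysis should find
TG/HDL-C and CMI the best discriminators, which is the recovery property
the test suite asserts (both outrank BMI, WtHR and ABSI by AUC in ≥90% of
200 seeds at n = 500).

**Fixture reference tables.** The percentile tables (waist, BP, lipids,
glucose, HOMA-IR p10/p90/p95 by sex at half-year knots, 6.5–18.5 y) are the
empirical percentiles of a *general-population* reference — the same
generative marginals with BMI-SDS ~ N(0, 1) and no latent risk — estimated
by deterministic Monte Carlo (4000 draws per knot). Building them from the
general population rather than from the high-adiposity cohort itself is
essential: it reproduces the clinical regime in which most PWS subjects
exceed the waist p90 of national references. The tables are synthetic
stand-ins for external growth/percentile publications and are not clinical
references.

**What the generator does not emulate:** genotype effects, growth-hormone
therapy, longitudinal trajectories, measurement error correlated across
centres, and multi-factor dependence between components (e.g. obesity →
dyslipidemia pathways beyond the shared risk state). Passing tests
therefore demonstrate the correctness and internal consistency of the
estimators under a known model, not clinical validity on real PWS data.

## Null-case semantics

With all effect sizes zero the latent risk state is independent of every
measurement, and every index has AUC ≈ 0.5 *against the latent label*. The
diagnosed MetS label is never a valid null reference, because the diagnosis
is computed from the same lipids, waist and BP the indices use.

## Numerical choices and degenerate inputs

- Interpolation of reference thresholds is linear in age; extrapolation is
  a coverage error.
- ROC analysis requires both classes; single-class strata are reported as
  explicitly undefined, and the CLI exits with code 3 on degenerate
  analyses (2 on schema errors).
- Simulation determinism: every stochastic routine takes or derives from a
  single integer seed; identical (config, seed, input) reruns produce
  byte-identical artifacts.
- Problem sizes in the test suite (200 seeds at n = 124 and n = 500 for
  calibration/recovery, 2×10⁴ for convergence checks, 2000-shuffle
  permutation cross-check) were chosen as the smallest sizes at which the
  Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

- The Wald interval is anti-conservative at extreme proportions and small
  n; it is the default because published screening tables are typically
  Wald-based, but Clopper–Pearson is one flag away.
- Youden-cutoff estimates at n ≈ 124 carry substantial sampling noise
  (SE ~ 0.05–0.1 in AUC terms); the age-resolved cutoff trend at such n is
  qualitative.
- The single-factor risk structure makes all between-component correlations
  positive; real cohorts show richer covariance.
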