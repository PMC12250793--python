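"""Synthetic PWS-like cohort generator and fixture reference tables.

The generator emulates the structure of a multicentre pediatric
Prader-Willi cohort: 124 children and adolescents aged 7-18, roughly even
sex split, high adiposity (median BMI-SDS ~ 2, ~55% obese), short stature
for age, and a metabolic-syndrome prevalence near 19%, concentrated among
the obese.  It is not a clinical growth model: its purpose is to provide a
cohort with *known* generative structure so the index computations, the
rule engine and the ROC machinery can be validated end to end.

Generative model
----------------
A single latent Bernoulli "high-risk" state drives all metabolic
components jointly: high-risk subjects get multiplicative (log-scale)
shifts on triglycerides, insulin and glucose, a negative shift on HDL-C,
and additive shifts on waist, blood pressure and BMI-SDS.  All continuous
biochemistry is log-normal; BMI is produced by inverting the shipped BMI
reference (so recomputed BMI-SDS recovers the generative z-score), weight
follows from BMI and height, and DXA masses split weight by a sex-specific
fat percentage (higher in girls).  Correlation between components arises
only through the shared risk state.

The fixture percentile tables are the empirical percentiles of the *healthy*
(risk = 0) subpopulation at each half-year age knot, computed by
deterministic Monte Carlo — so "waist > p90" has its literal meaning within
the generative world.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .indices import Sex
from .io import COHORT_COLUMNS
from .references import (PercentileReferenceProvider, TableBmiReference,
                         reference_objects_from_frame)

__all__ = [
    "RiskEffects",
    "CohortParams",
    "simulate_cohort",
    "simulate_cohort_with_latent",
    "make_reference_frame",
    "make_reference_tables",
    "true_auc_oracle",
]


@dataclass(frozen=True)
class RiskEffects:
    """Shifts applied to high-risk subjects, per MetS component.

    Log-scale (multiplicative) for the log-normal biochemistry, additive in
    the measured unit otherwise.  Defaults are lipid-dominant: the risk
    state moves triglycerides and HDL-C much further (in SD units) than
    waist or blood pressure, mirroring a population where dyslipidemia is
    the most discriminative component.
    """

    tg_log: float = 0.65
    hdl_log: float = -0.33
    insulin_log: float = 0.55
    glucose_log: float = 0.07
    hba1c_log: float = 0.03
    nonhdl_log: float = 0.08
    waist_cm: float = 2.5
    sbp_mmhg: float = 6.0
    dbp_mmhg: float = 7.0
    bmi_sds: float = 0.55

    @classmethod
    def null(cls) -> "RiskEffects":
        """All-zero effects: the risk label carries no signal."""
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__})


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for one simulated cohort.

    Location/spread defaults target the medians and ranges of a PWS
    pediatric cohort (median BMI ~26 kg/m², TG ~77, HDL ~52, glucose ~80
    mg/dL, SBP ~111 mmHg); ``risk_prob`` is calibrated so the realized MetS
    prevalence at the defaults is ~19%.
    """

    n: int = 124
    female_fraction: float = 61.0 / 124.0
    age_min: float = 7.0
    age_max: float = 18.0
    risk_prob: float = 0.46
    effects: RiskEffects = field(default_factory=RiskEffects)
    seed: int = 0

    # healthy-population marginals (medians / spreads)
    bmi_sds_mean: float = 1.85
    bmi_sds_sd: float = 1.30
    height_sd_cm: float = 7.0
    waist_noise_sd_cm: float = 4.0
    tg_median: float = 72.0
    tg_log_sd: float = 0.45
    hdl_median: float = 54.0
    hdl_log_sd: float = 0.21
    nonhdl_median: float = 112.0
    nonhdl_log_sd: float = 0.25
    glucose_median_f: float = 78.0
    glucose_median_m: float = 81.5
    glucose_log_sd: float = 0.075
    insulin_median: float = 9.8
    insulin_log_sd: float = 0.55
    hba1c_median: float = 5.35
    hba1c_log_sd: float = 0.055
    sbp_mean: float = 109.0
    sbp_age_slope: float = 0.6
    sbp_sd: float = 9.0
    dbp_mean: float = 68.5
    dbp_sd: float = 8.0
    fm_pct_female: float = 48.5
    fm_pct_male: float = 45.1
    fm_pct_sd: float = 6.0

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError(f"cohort size must be >= 2, got {self.n}")
        if not (0.0 < self.risk_prob < 1.0):
            raise ConfigError(f"risk_prob must be in (0, 1), got {self.risk_prob}")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ConfigError("female_fraction must be in [0, 1]")
        if not (self.age_min < self.age_max):
            raise ConfigError("age_min must be below age_max")
        for name in ("bmi_sds_sd", "height_sd_cm", "waist_noise_sd_cm",
                     "tg_log_sd", "hdl_log_sd", "nonhdl_log_sd",
                     "glucose_log_sd", "insulin_log_sd", "hba1c_log_sd",
                     "sbp_sd", "dbp_sd", "fm_pct_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"spread parameter {name} must be positive")


# --- growth curves (synthetic; short-for-age as in PWS) --------------------

def _height_median(age: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Median height (cm) by age/sex: linear growth 7 -> 18 y."""
    frac = (np.asarray(age, dtype=float) - 7.0) / 11.0
    h_f = 120.0 + 38.0 * frac
    h_m = 121.0 + 47.0 * frac
    return np.where(female, h_f, h_m)


def _bmi_median(age: np.ndarray) -> np.ndarray:
    """Median BMI (kg/m²) by age (sex-invariant in the fixture)."""
    return 16.0 + 5.5 * (np.asarray(age, dtype=float) - 7.0) / 11.0


def _bmi_sd(age: np.ndarray) -> np.ndarray:
    """Absolute BMI SD by age."""
    return 2.2 + 2.0 * (np.asarray(age, dtype=float) - 7.0) / 11.0


def _tanner_from_age(age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    stage = 1 + np.floor((age - 8.5) / 2.2) + rng.integers(-1, 2, size=age.size)
    return np.clip(stage, 1, 5).astype(int)


def _draw_measurements(rng: np.random.Generator, params: CohortParams,
                       ages: np.ndarray, female: np.ndarray,
                       risk: np.ndarray) -> dict[str, np.ndarray]:
    """Draw all continuous measurements for subjects with given age/sex/risk."""
    p, e = params, params.effects
    n = ages.size
    risk = risk.astype(float)

    height = _height_median(ages, female) + rng.normal(0.0, p.height_sd_cm, n)
    height = np.maximum(height, 95.0)

    bmi_sds = rng.normal(p.bmi_sds_mean, p.bmi_sds_sd, n) + e.bmi_sds * risk
    bmi = np.maximum(_bmi_median(ages) + bmi_sds * _bmi_sd(ages), 13.0)
    weight = bmi * (height / 100.0) ** 2

    waist = (height * (0.28 + 0.011 * bmi)
             + rng.normal(0.0, p.waist_noise_sd_cm, n) + e.waist_cm * risk)
    waist = np.maximum(waist, 0.30 * height)

    fm_base = np.where(female, p.fm_pct_female, p.fm_pct_male)
    fm_pct = np.clip(fm_base + 1.5 * (bmi_sds - 2.0)
                     + rng.normal(0.0, p.fm_pct_sd, n), 12.0, 64.0)
    fm = fm_pct / 100.0 * weight
    ffm = weight - fm

    tg = np.exp(np.log(p.tg_median) + rng.normal(0.0, p.tg_log_sd, n)
                + e.tg_log * risk)
    hdl = np.exp(np.log(p.hdl_median) + rng.normal(0.0, p.hdl_log_sd, n)
                 + e.hdl_log * risk)
    nonhdl = np.exp(np.log(p.nonhdl_median) + rng.normal(0.0, p.nonhdl_log_sd, n)
                    + e.nonhdl_log * risk)
    tc = hdl + nonhdl

    glucose_median = np.where(female, p.glucose_median_f, p.glucose_median_m)
    glucose = np.exp(np.log(glucose_median) + rng.normal(0.0, p.glucose_log_sd, n)
                     + e.glucose_log * risk)
    insulin = np.exp(np.log(p.insulin_median) + rng.normal(0.0, p.insulin_log_sd, n)
                     + e.insulin_log * risk + 0.12 * (bmi_sds - 2.0))
    insulin = np.maximum(insulin, 0.5)
    hba1c = np.exp(np.log(p.hba1c_median) + rng.normal(0.0, p.hba1c_log_sd, n)
                   + e.hba1c_log * risk)

    sbp = (p.sbp_mean + p.sbp_age_slope * (ages - 13.0)
           + rng.normal(0.0, p.sbp_sd, n) + e.sbp_mmhg * risk)
    dbp = p.dbp_mean + rng.normal(0.0, p.dbp_sd, n) + e.dbp_mmhg * risk
    dbp = np.minimum(dbp, sbp - 15.0)
    sbp = np.maximum(sbp, 70.0)
    dbp = np.maximum(dbp, 35.0)

    return {
        "height_cm": height, "weight_kg": weight, "waist_cm": waist,
        "fm_kg": fm, "ffm_kg": ffm, "tg_mgdl": tg, "hdl_mgdl": hdl,
        "tc_mgdl": tc, "glucose_mgdl": glucose, "insulin_uUml": insulin,
        "hba1c_pct": hba1c, "sbp_mmhg": sbp, "dbp_mmhg": dbp,
    }


def simulate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Simulate one cohort in the standard CSV schema; deterministic by seed."""
    df, _ = simulate_cohort_with_latent(params)
    return df


def simulate_cohort_with_latent(
    params: CohortParams | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """As :func:`simulate_cohort`, also returning the latent risk states.

    The boolean risk vector is the generative ground truth behind the
    metabolic shifts; with null effects it is independent of every
    measurement, which is the natural label for null-case checks (the
    *diagnosed* MetS label is never independent of the lipids and waist it
    is defined from).
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    female = rng.random(n) < params.female_fraction
    ages = rng.uniform(params.age_min, params.age_max, n)
    risk = rng.random(n) < params.risk_prob
    m = _draw_measurements(rng, params, ages, female, risk)

    dx_igt = rng.random(n) < (0.01 + 0.14 * risk)
    rx_bp = rng.random(n) < (0.005 + 0.06 * risk)
    rx_lipid = rng.random(n) < (0.004 + 0.02 * risk)

    df = pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "age_years": np.round(ages, 2),
        "sex": np.where(female, "F", "M"),
        "tanner": _tanner_from_age(ages, rng),
        "weight_kg": np.round(m["weight_kg"], 1),
        "height_cm": np.round(m["height_cm"], 1),
        "waist_cm": np.round(m["waist_cm"], 1),
        "fm_kg": np.round(m["fm_kg"], 1),
        "ffm_kg": np.round(m["ffm_kg"], 1),
        "glucose_mgdl": np.round(m["glucose_mgdl"], 0),
        "insulin_uUml": np.round(m["insulin_uUml"], 1),
        "hba1c_pct": np.round(m["hba1c_pct"], 1),
        "tc_mgdl": np.round(m["tc_mgdl"], 0),
        "hdl_mgdl": np.round(m["hdl_mgdl"], 0),
        "tg_mgdl": np.round(m["tg_mgdl"], 0),
        "sbp_mmhg": np.round(m["sbp_mmhg"], 0),
        "dbp_mmhg": np.round(m["dbp_mmhg"], 0),
        "rx_lipid": rx_lipid.astype(int),
        "rx_bp": rx_bp.astype(int),
        "dx_igt_t2dm": dx_igt.astype(int),
    })
    return df[COHORT_COLUMNS], risk


# --- fixture reference tables ----------------------------------------------

_KNOTS = np.arange(6.5, 18.51, 0.5)
_MC_PER_KNOT = 4000


def make_reference_frame(seed: int = 0,
                         params: CohortParams | None = None) -> pd.DataFrame:
    """Long-format reference table (BMI L/M/S plus component percentiles).

    BMI rows restate the generator's own growth reference (L = 1, absolute
    SD).  Percentile rows emulate *general-population* norms: they are the
    empirical p10/p90/p95, at each half-year knot, of a reference population
    with BMI-SDS ~ N(0, 1) and no latent metabolic risk — not of the
    (high-adiposity) cohort itself, which is why most simulated PWS-like
    subjects exceed the waist p90, as real PWS cohorts do against national
    references.  Monte-Carlo estimated with a rng derived deterministically
    from ``seed``; identical seeds give byte-identical tables.
    """
    params = replace(params or CohortParams(), bmi_sds_mean=0.0, bmi_sds_sd=1.0)
    rows = []
    for sex in (Sex.FEMALE, Sex.MALE):
        female_flag = sex is Sex.FEMALE
        for age in _KNOTS:
            rows.append({
                "sex": sex.value, "age_years": float(age), "variable": "bmi",
                "L": 1.0, "M": float(_bmi_median(np.array([age]))[0]),
                "S": float(_bmi_sd(np.array([age]))[0]),
                "p10": np.nan, "p90": np.nan, "p95": np.nan,
            })
        # one rng per sex so the table is independent of knot iteration order
        rng = np.random.default_rng([seed, 17, int(female_flag)])
        for age in _KNOTS:
            ages = np.full(_MC_PER_KNOT, float(age))
            female = np.full(_MC_PER_KNOT, female_flag)
            healthy = np.zeros(_MC_PER_KNOT, dtype=bool)
            m = _draw_measurements(rng, params, ages, female, healthy)
            homa = m["glucose_mgdl"] * m["insulin_uUml"] / 405.0
            for variable, values in (
                ("wc", m["waist_cm"]), ("sbp", m["sbp_mmhg"]),
                ("dbp", m["dbp_mmhg"]), ("tg", m["tg_mgdl"]),
                ("hdl", m["hdl_mgdl"]), ("glucose", m["glucose_mgdl"]),
                ("homa", homa),
            ):
                p10, p90, p95 = np.percentile(values, [10, 90, 95])
                rows.append({
                    "sex": sex.value, "age_years": float(age),
                    "variable": variable, "L": np.nan, "M": np.nan, "S": np.nan,
                    "p10": round(float(p10), 3), "p90": round(float(p90), 3),
                    "p95": round(float(p95), 3),
                })
    return pd.DataFrame(rows)


def make_reference_tables(
    seed: int = 0, params: CohortParams | None = None,
) -> tuple[TableBmiReference, PercentileReferenceProvider]:
    """Fixture BMI reference and percentile provider (see make_reference_frame)."""
    return reference_objects_from_frame(make_reference_frame(seed, params))


def true_auc_oracle(params: CohortParams | None = None, *, n: int = 100_000,
                    seed: int = 12345) -> dict[str, float]:
    """Monte-Carlo estimate of each index's population AUC for MetS.

    Simulates a large cohort under ``params``, classifies it with the
    fixture references, and returns rank-based AUCs keyed by index name.
    Used as ground truth in recovery tests; DXA-free by construction (all
    synthetic records carry DXA masses).
    """
    from .diagnostics import ScoredCohort, auc_rank
    from .pipeline import classify_frame, index_frame

    params = replace(params or CohortParams(), n=n, seed=seed)
    df = simulate_cohort(params)
    bmi_ref, provider = make_reference_tables(params.seed, params)
    panels = index_frame(df, bmi_ref)
    labels = classify_frame(df, panels, provider)["mets"].to_numpy()
    out = {}
    for name in panels.columns:
        if name in ("id",):
            continue
        scores = panels[name].to_numpy(dtype=float)
        out[name] = auc_rank(ScoredCohort(scores, labels)).value
    return out
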