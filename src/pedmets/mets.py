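"""Age-dispatched metabolic-syndrome (MetS) rule engine.

Three criteria sets are applied by age band, half-open at the boundaries:

* 7 <= age < 10 — IDEFICS-style: four components scored against age/sex
  percentile thresholds (waist > p90; systolic or diastolic BP > p90;
  TG > p90 or HDL-C < p10; HOMA-IR > p90 or fasting glucose > p90).
  MetS requires at least three of the four components.
* 10 <= age < 16 — IDF-style: mandatory abdominal-obesity gate
  (waist > p90) plus at least two of: TG > 150 mg/dL; HDL-C < 40 mg/dL
  (both sexes); SBP > 130 or DBP > 85 mmHg; fasting glucose > 100 mg/dL or
  previously diagnosed IGT/T2DM.
* age >= 16 — IDF adult-style: waist gate at absolute cuts (> 94 cm males,
  > 80 cm females); factor thresholds as above except HDL-C < 40 (males) /
  < 50 (females) mg/dL, and specific treatment substitutes for the lipid
  and BP factors.

Every threshold comparison is strict, so a value exactly at a cutoff is
non-pathological.  A previously diagnosed IGT/T2DM counts as the glucose
factor at every age; lipid/BP treatment overrides apply only in the >= 16
band.  Treatment for a lipid abnormality counts as a single lipid factor by
default (``treated_lipids_double_count=True`` counts it as both the TG and
the HDL factor for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import UnsupportedAgeError
from .indices import IndexPanel, Sex, SubjectRecord
from .references import PercentileReferenceProvider

__all__ = [
    "CriteriaSet",
    "MetSResult",
    "classify_weight_status",
    "diagnose_idefics",
    "diagnose_idf_10_16",
    "diagnose_idf_16plus",
    "diagnose_mets",
    "combine_idefics",
    "combine_idf",
]

# Absolute factor thresholds shared by the IDF-style bands.
TG_CUT_MGDL = 150.0
HDL_CUT_MGDL = 40.0
HDL_CUT_FEMALE_16PLUS_MGDL = 50.0
SBP_CUT_MMHG = 130.0
DBP_CUT_MMHG = 85.0
GLUCOSE_CUT_MGDL = 100.0
WC_CUT_MALE_16PLUS_CM = 94.0
WC_CUT_FEMALE_16PLUS_CM = 80.0

OBESITY_BMI_SDS_CUT = 2.0


class CriteriaSet(str, Enum):
    IDEFICS = "IDEFICS"
    IDF_10_16 = "IDF_10_16"
    IDF_16PLUS = "IDF_16PLUS"


@dataclass(frozen=True)
class MetSResult:
    """Per-component pathology flags and the binary diagnosis.

    ``n_components`` counts components per the applicable rule: the IDEFICS
    set pools TG/HDL into one lipid component and HOMA/glucose into one
    dysglycemia component (waist, BP, lipid, glucose => 0-4); the IDF sets
    count the four non-gate factors (TG, HDL, BP, glucose => 0-4), with the
    waist gate recorded separately in ``abdominal_obesity``.
    """

    subject_id: str
    criteria_set: CriteriaSet
    abdominal_obesity: bool
    bp_flag: bool
    lipid_tg_flag: bool
    lipid_hdl_flag: bool
    glucose_flag: bool
    n_components: int
    mets: bool


def classify_weight_status(bmi_sds: float) -> str:
    """'obese' iff BMI-SDS strictly exceeds 2.0, else 'non_obese'."""
    return "obese" if bmi_sds > OBESITY_BMI_SDS_CUT else "non_obese"


def combine_idefics(wc: bool, bp: bool, lipid: bool, glucose: bool) -> tuple[int, bool]:
    """IDEFICS combination rule: (component count, diagnosis at >= 3)."""
    n = int(wc) + int(bp) + int(lipid) + int(glucose)
    return n, n >= 3


def combine_idf(gate: bool, tg: bool, hdl: bool, bp: bool,
                glucose: bool) -> tuple[int, bool]:
    """IDF combination rule: mandatory gate plus >= 2 of the four factors."""
    n = int(tg) + int(hdl) + int(bp) + int(glucose)
    return n, gate and n >= 2


def diagnose_idefics(subject: SubjectRecord, panel: IndexPanel,
                     ref: PercentileReferenceProvider) -> MetSResult:
    """Percentile-based component scoring for ages 7 to <10 years."""
    sex, age = subject.sex, subject.age
    wc = subject.waist > ref.wc_p90(sex, age)
    bp = (subject.sbp > ref.sbp_p90(sex, age)) or (subject.dbp > ref.dbp_p90(sex, age))
    tg = subject.tg > ref.tg_p90(sex, age)
    hdl = subject.hdl < ref.hdl_p10(sex, age)
    glucose = (
        panel.homa_ir > ref.homa_p90(sex, age)
        or subject.glucose > ref.glucose_p90(sex, age)
        or subject.diagnosed_igt_t2dm
    )
    n, mets = combine_idefics(wc, bp, tg or hdl, glucose)
    return MetSResult(subject.id, CriteriaSet.IDEFICS, wc, bp, tg, hdl,
                      glucose, n, mets)


def diagnose_idf_10_16(subject: SubjectRecord, panel: IndexPanel,
                       ref: PercentileReferenceProvider,
                       *, treated_lipids_double_count: bool = False) -> MetSResult:
    """IDF scoring with the percentile waist gate for ages 10 to <16 years."""
    sex, age = subject.sex, subject.age
    gate = subject.waist > ref.wc_p90(sex, age)
    tg = subject.tg > TG_CUT_MGDL
    hdl = subject.hdl < HDL_CUT_MGDL
    bp = subject.sbp > SBP_CUT_MMHG or subject.dbp > DBP_CUT_MMHG
    glucose = subject.glucose > GLUCOSE_CUT_MGDL or subject.diagnosed_igt_t2dm
    n, mets = combine_idf(gate, tg, hdl, bp, glucose)
    return MetSResult(subject.id, CriteriaSet.IDF_10_16, gate, bp, tg, hdl,
                      glucose, n, mets)


def diagnose_idf_16plus(subject: SubjectRecord, panel: IndexPanel,
                        ref: PercentileReferenceProvider,
                        *, treated_lipids_double_count: bool = False) -> MetSResult:
    """IDF adult-style scoring with absolute waist cuts for ages >= 16 years."""
    if subject.sex is Sex.MALE:
        gate = subject.waist > WC_CUT_MALE_16PLUS_CM
        hdl_cut = HDL_CUT_MGDL
    else:
        gate = subject.waist > WC_CUT_FEMALE_16PLUS_CM
        hdl_cut = HDL_CUT_FEMALE_16PLUS_MGDL
    tg_measured = subject.tg > TG_CUT_MGDL
    hdl_measured = subject.hdl < hdl_cut
    if treated_lipids_double_count:
        tg = tg_measured or subject.on_lipid_treatment
        hdl = hdl_measured or subject.on_lipid_treatment
    else:
        # treatment contributes at most one lipid factor; attach it to the TG
        # slot unless the HDL abnormality is itself measured
        tg = tg_measured or (subject.on_lipid_treatment and not hdl_measured)
        hdl = hdl_measured
    bp = (subject.sbp > SBP_CUT_MMHG or subject.dbp > DBP_CUT_MMHG
          or subject.on_bp_treatment)
    glucose = subject.glucose > GLUCOSE_CUT_MGDL or subject.diagnosed_igt_t2dm
    n, mets = combine_idf(gate, tg, hdl, bp, glucose)
    return MetSResult(subject.id, CriteriaSet.IDF_16PLUS, gate, bp, tg, hdl,
                      glucose, n, mets)


def diagnose_mets(subject: SubjectRecord, panel: IndexPanel,
                  ref: PercentileReferenceProvider,
                  *, treated_lipids_double_count: bool = False) -> MetSResult:
    """Dispatch to the criteria set for the subject's age band.

    Bands are left-closed/right-open: [7, 10) IDEFICS, [10, 16) IDF with the
    percentile gate, [16, inf) IDF with absolute waist cuts.
    """
    age = subject.age
    if age < 7:
        raise UnsupportedAgeError(
            f"no MetS criteria defined below age 7 (subject {subject.id}, age {age:g})"
        )
    if age < 10:
        return diagnose_idefics(subject, panel, ref)
    if age < 16:
        return diagnose_idf_10_16(
            subject, panel, ref,
            treated_lipids_double_count=treated_lipids_double_count)
    return diagnose_idf_16plus(
        subject, panel, ref,
        treated_lipids_double_count=treated_lipids_double_count)
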