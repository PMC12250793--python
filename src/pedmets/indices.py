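"""Anthropometric, body-composition and lipid-derived cardiometabolic indices.

All functions take measurements in the clinical units they are recorded in
(weight kg, height cm, waist cm, lipids mg/dL unless stated otherwise) and
document the unit convention of the result.  Composite indices that mix
units (ABSI, BMFI) normalise lengths to metres and fat mass to a fraction so
the results land on the scale conventionally reported for children and
adolescents (ABSI ~ 0.08, BMFI ~ 10).

The visceral adiposity index (VAI) follows the original sex-specific
definition with the waist term normalised by ``39.68 + 1.88*BMI`` (males)
and ``36.58 + 1.89*BMI`` (females); a frequently reprinted mis-parenthesised
variant (``WC/39.68 + 1.88*BMI``) is available behind an explicit flag for
sensitivity analysis only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Protocol

from .errors import CoverageError, DomainError, MissingDataError

__all__ = [
    "Sex",
    "SubjectRecord",
    "IndexPanel",
    "BmiReference",
    "MGDL_PER_MMOL_TG",
    "MGDL_PER_MMOL_CHOL",
    "tg_mgdl_to_mmol",
    "chol_mgdl_to_mmol",
    "compute_bmi",
    "compute_bmi_sds",
    "compute_tmi",
    "compute_fmi",
    "compute_ffmi",
    "compute_bmfi",
    "compute_absi",
    "compute_vai",
    "compute_wthr",
    "compute_cmi",
    "compute_lipid_ratios",
    "compute_homa_ir",
    "compute_all_indices",
    "INDEX_NAMES",
]

# Conventional conversion factors between mass and molar lipid units.
MGDL_PER_MMOL_TG = 88.57
MGDL_PER_MMOL_CHOL = 38.67


def tg_mgdl_to_mmol(tg_mgdl: float) -> float:
    """Triglycerides mg/dL -> mmol/L."""
    return tg_mgdl / MGDL_PER_MMOL_TG


def chol_mgdl_to_mmol(chol_mgdl: float) -> float:
    """Cholesterol (total or HDL) mg/dL -> mmol/L."""
    return chol_mgdl / MGDL_PER_MMOL_CHOL


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().upper()
        if v in ("F", "FEMALE"):
            return cls.FEMALE
        if v in ("M", "MALE"):
            return cls.MALE
        raise DomainError("sex", f"unrecognised sex {value!r} (expected F or M)")


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise DomainError(name, f"must be strictly positive and finite, got {value!r}")


@dataclass
class SubjectRecord:
    """One child/adolescent's anthropometric, biochemical and treatment data.

    Units: age years, weight kg, height/waist cm, masses kg, glucose mg/dL,
    insulin µU/mL, HbA1c %, lipids mg/dL, blood pressure mmHg.
    """

    id: str
    age: float
    sex: Sex
    weight: float
    height: float
    waist: float
    glucose: float
    insulin: float
    total_chol: float
    hdl: float
    tg: float
    sbp: float
    dbp: float
    tanner: Optional[int] = None
    fat_mass: Optional[float] = None
    fat_free_mass: Optional[float] = None
    hba1c: Optional[float] = None
    on_lipid_treatment: bool = False
    on_bp_treatment: bool = False
    diagnosed_igt_t2dm: bool = False

    def __post_init__(self) -> None:
        self.sex = Sex.parse(self.sex)
        if not (0.0 <= self.age <= 25.0):
            raise DomainError("age", f"must be in [0, 25] years, got {self.age!r}")
        for name in ("weight", "height", "waist", "glucose", "insulin",
                     "total_chol", "hdl", "tg", "sbp", "dbp"):
            _require_positive(name, getattr(self, name))
        for name in ("fat_mass", "fat_free_mass", "hba1c"):
            v = getattr(self, name)
            if v is not None:
                _require_positive(name, v)
        if self.tanner is not None and self.tanner not in (1, 2, 3, 4, 5):
            raise DomainError("tanner", f"must be an integer 1-5, got {self.tanner!r}")
        if self.fat_mass is not None and self.fat_free_mass is not None:
            # 5% headroom: DXA masses and scale weight come from different devices
            if self.fat_mass + self.fat_free_mass > self.weight * 1.05:
                raise DomainError(
                    "fat_mass",
                    "fat_mass + fat_free_mass exceeds weight by more than 5%",
                )

    @property
    def fm_fraction(self) -> Optional[float]:
        """Fat mass as a fraction of body weight, or None without DXA."""
        if self.fat_mass is None:
            return None
        return self.fat_mass / self.weight


class BmiReference(Protocol):
    """Lookup contract mapping (sex, age) to BMI reference parameters.

    ``lookup`` returns ``(L, M, S)``: the median ``M``, the spread ``S`` and
    the skewness ``L`` (``None`` when the reference is a plain mean/SD
    table).  When ``L`` is ``None`` or exactly 1 the reference is treated as
    normal with absolute SD ``S``; otherwise the Box-Cox (LMS) transform is
    applied with ``S`` interpreted as a coefficient of variation.
    Implementations raise :class:`CoverageError` outside their age range.
    """

    def lookup(self, sex: Sex, age: float) -> tuple[Optional[float], float, float]:
        ...


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight (kg) and height (cm)."""
    _require_positive("weight", weight)
    _require_positive("height", height)
    h_m = height / 100.0
    return weight / (h_m * h_m)


def compute_bmi_sds(bmi: float, sex: Sex, age: float, ref: BmiReference) -> float:
    """BMI standard-deviation score against an age/sex reference.

    With skewness ``L`` absent or equal to 1 the score is ``(bmi - M)/S``
    with ``S`` an absolute SD; with a genuine Box-Cox ``L`` the LMS
    transform ``((bmi/M)**L - 1)/(L*S)`` is used (``ln(bmi/M)/S`` at L=0),
    ``S`` being a coefficient of variation per growth-chart convention.
    """
    _require_positive("bmi", bmi)
    L, M, S = ref.lookup(Sex.parse(sex), age)
    if not (M > 0 and S > 0):
        raise CoverageError(f"reference returned non-positive M/S at age {age}")
    if L is None or L == 1:
        return (bmi - M) / S
    if L == 0:
        return math.log(bmi / M) / S
    return ((bmi / M) ** L - 1.0) / (L * S)


def compute_tmi(weight: float, height: float) -> float:
    """Tri-ponderal mass index, kg/m³."""
    _require_positive("weight", weight)
    _require_positive("height", height)
    return weight / (height / 100.0) ** 3


def compute_fmi(fat_mass: Optional[float], height: float) -> float:
    """Fat-mass index, kg/m² (DXA fat mass over squared height)."""
    if fat_mass is None:
        raise MissingDataError("fat_mass")
    _require_positive("fat_mass", fat_mass)
    _require_positive("height", height)
    return fat_mass / (height / 100.0) ** 2


def compute_ffmi(fat_free_mass: Optional[float], height: float) -> float:
    """Fat-free-mass index, kg/m²."""
    if fat_free_mass is None:
        raise MissingDataError("fat_free_mass")
    _require_positive("fat_free_mass", fat_free_mass)
    _require_positive("height", height)
    return fat_free_mass / (height / 100.0) ** 2


def compute_bmfi(bmi: float, fm_fraction: float, waist: float) -> float:
    """Body-mass-fat index: BMI x fat-mass fraction x waist in metres.

    ``fm_fraction`` must be a fraction in (0, 1); passing a percentage is a
    domain error rather than a silent factor-of-100 slip.
    """
    _require_positive("bmi", bmi)
    _require_positive("waist", waist)
    if not (0.0 < fm_fraction < 1.0):
        raise DomainError(
            "fm_fraction",
            f"must be a fraction in (0, 1), got {fm_fraction!r} "
            "(did you pass a percentage?)",
        )
    return bmi * fm_fraction * (waist / 100.0)


def compute_absi(waist: float, bmi: float, height: float) -> float:
    """A body shape index: waist_m / (BMI^(2/3) * height_m^(1/2)).

    Isolates central adiposity from overall size; ~0.08 in children.
    """
    _require_positive("waist", waist)
    _require_positive("bmi", bmi)
    _require_positive("height", height)
    return (waist / 100.0) / (bmi ** (2.0 / 3.0) * (height / 100.0) ** 0.5)


def compute_vai(sex: Sex, waist: float, bmi: float, tg_mmol: float,
                hdl_mmol: float, *, literal_parenthesisation: bool = False) -> float:
    """Visceral adiposity index (sex-specific; lipids in mmol/L).

    Males:   WC/(39.68 + 1.88*BMI) * (TG/1.03) * (1.31/HDL)
    Females: WC/(36.58 + 1.89*BMI) * (TG/0.81) * (1.52/HDL)

    ``literal_parenthesisation=True`` evaluates the waist term as
    ``WC/39.68 + 1.88*BMI`` instead — a reading seen in some reprints of the
    formula, offered only for sensitivity analysis (it inflates the index by
    roughly two orders of magnitude).
    """
    _require_positive("waist", waist)
    _require_positive("bmi", bmi)
    _require_positive("tg_mmol", tg_mmol)
    _require_positive("hdl_mmol", hdl_mmol)
    sex = Sex.parse(sex)
    if sex is Sex.MALE:
        waist_term = (waist / 39.68 + 1.88 * bmi) if literal_parenthesisation \
            else waist / (39.68 + 1.88 * bmi)
        return waist_term * (tg_mmol / 1.03) * (1.31 / hdl_mmol)
    waist_term = (waist / 36.58 + 1.89 * bmi) if literal_parenthesisation \
        else waist / (36.58 + 1.89 * bmi)
    return waist_term * (tg_mmol / 0.81) * (1.52 / hdl_mmol)


def compute_wthr(waist: float, height: float) -> float:
    """Waist-to-height ratio (both cm)."""
    _require_positive("waist", waist)
    _require_positive("height", height)
    return waist / height


def compute_cmi(wthr: float, tg_hdl: float) -> float:
    """Cardiometabolic index: waist-to-height ratio x TG/HDL-C ratio."""
    if wthr < 0:
        raise DomainError("wthr", "must be nonnegative")
    if tg_hdl < 0:
        raise DomainError("tg_hdl", "must be nonnegative")
    return wthr * tg_hdl


def compute_lipid_ratios(total_chol: float, hdl: float, tg: float) -> tuple[float, float]:
    """(TC/HDL-C, TG/HDL-C); unit-free since numerators share the HDL unit."""
    if not (hdl > 0):
        raise DomainError("hdl", "must be strictly positive")
    if total_chol < 0 or tg < 0:
        raise DomainError("lipids", "must be nonnegative")
    return total_chol / hdl, tg / hdl


def compute_homa_ir(glucose: float, insulin: float) -> float:
    """HOMA-IR = fasting glucose (mg/dL) x fasting insulin (µU/mL) / 405."""
    _require_positive("glucose", glucose)
    _require_positive("insulin", insulin)
    return glucose * insulin / 405.0


# Canonical ordering of the panel's score columns (used by CLI and pipeline).
INDEX_NAMES = ("bmi", "bmi_sds", "tmi", "bmfi", "fmi", "ffmi", "absi", "vai",
               "wthr", "cmi", "tc_hdl", "tg_hdl")


@dataclass
class IndexPanel:
    """The twelve indices plus HOMA-IR for one subject.

    Fields requiring absent optional measurements (DXA masses) are ``None``,
    never silently zero.
    """

    bmi: float
    bmi_sds: float
    tmi: float
    absi: float
    vai: float
    wthr: float
    cmi: float
    tc_hdl: float
    tg_hdl: float
    homa_ir: float
    bmfi: Optional[float] = None
    fmi: Optional[float] = None
    ffmi: Optional[float] = None
    subject_id: Optional[str] = field(default=None, compare=False)

    def get(self, name: str) -> Optional[float]:
        if name not in INDEX_NAMES and name != "homa_ir":
            raise KeyError(name)
        return getattr(self, name)


def compute_all_indices(subject: SubjectRecord, ref: BmiReference,
                        *, vai_literal: bool = False) -> IndexPanel:
    """Compute every index the subject's data supports.

    DXA-dependent indices (FMI, FFMI, BMFI) are left undefined when the
    corresponding mass is absent; everything else is always computed.
    """
    bmi = compute_bmi(subject.weight, subject.height)
    tc_hdl, tg_hdl = compute_lipid_ratios(subject.total_chol, subject.hdl, subject.tg)
    wthr = compute_wthr(subject.waist, subject.height)
    panel = IndexPanel(
        bmi=bmi,
        bmi_sds=compute_bmi_sds(bmi, subject.sex, subject.age, ref),
        tmi=compute_tmi(subject.weight, subject.height),
        absi=compute_absi(subject.waist, bmi, subject.height),
        vai=compute_vai(subject.sex, subject.waist, bmi,
                        tg_mgdl_to_mmol(subject.tg), chol_mgdl_to_mmol(subject.hdl),
                        literal_parenthesisation=vai_literal),
        wthr=wthr,
        cmi=compute_cmi(wthr, tg_hdl),
        tc_hdl=tc_hdl,
        tg_hdl=tg_hdl,
        homa_ir=compute_homa_ir(subject.glucose, subject.insulin),
        subject_id=subject.id,
    )
    if subject.fat_mass is not None:
        panel.fmi = compute_fmi(subject.fat_mass, subject.height)
        panel.bmfi = compute_bmfi(bmi, subject.fm_fraction, subject.waist)
    if subject.fat_free_mass is not None:
        panel.ffmi = compute_ffmi(subject.fat_free_mass, subject.height)
    return panel
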