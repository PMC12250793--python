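"""Age/sex-indexed reference tables: BMI growth reference and percentile
thresholds for the metabolic-syndrome components.

Tables are consumed from a long-format CSV with one row per (sex, age knot,
variable).  Columns::

    sex, age_years, variable, L, M, S, p10, p90, p95

``variable == "bmi"`` rows carry L/M/S growth-reference parameters; the
component-threshold variables (``wc``, ``sbp``, ``dbp``, ``tg``, ``hdl``,
``homa``, ``glucose``) carry percentile columns in the measured unit.
Thresholds are linearly interpolated in age between tabulated knots within
each sex; a query outside the tabulated age range raises
:class:`~pedmets.errors.CoverageError` rather than clamping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CoverageError, SchemaError
from .indices import Sex

__all__ = [
    "TableBmiReference",
    "PercentileReferenceProvider",
    "load_reference_tables",
    "REFERENCE_COLUMNS",
]

REFERENCE_COLUMNS = ["sex", "age_years", "variable", "L", "M", "S", "p10", "p90", "p95"]


class _AgeCurve:
    """A piecewise-linear curve over age knots for one (sex, variable)."""

    def __init__(self, ages: np.ndarray, values: np.ndarray, label: str):
        order = np.argsort(ages)
        self.ages = np.asarray(ages, dtype=float)[order]
        self.values = np.asarray(values, dtype=float)[order]
        self.label = label
        if len(self.ages) < 2:
            raise SchemaError(f"reference curve {label} needs >= 2 age knots")
        if np.any(np.diff(self.ages) <= 0):
            raise SchemaError(f"reference curve {label} has duplicate age knots")

    def __call__(self, age: float) -> float:
        if not (self.ages[0] <= age <= self.ages[-1]):
            raise CoverageError(
                f"age {age:g} outside reference coverage "
                f"[{self.ages[0]:g}, {self.ages[-1]:g}] for {self.label}"
            )
        return float(np.interp(age, self.ages, self.values))


@dataclass(frozen=True)
class TableBmiReference:
    """BMI growth reference backed by per-sex age curves for L, M, S."""

    _curves: dict  # (sex, param) -> _AgeCurve; param in {"L","M","S"}

    def lookup(self, sex: Sex, age: float) -> tuple[Optional[float], float, float]:
        sex = Sex.parse(sex)
        M = self._curves[(sex, "M")](age)
        S = self._curves[(sex, "S")](age)
        L_curve = self._curves.get((sex, "L"))
        L = L_curve(age) if L_curve is not None else None
        return L, M, S


_PROVIDER_CURVES = {
    # method name -> (variable, percentile column)
    "wc_p90": ("wc", "p90"),
    "sbp_p90": ("sbp", "p90"),
    "dbp_p90": ("dbp", "p90"),
    "tg_p90": ("tg", "p90"),
    "hdl_p10": ("hdl", "p10"),
    "homa_p90": ("homa", "p90"),
    "glucose_p90": ("glucose", "p90"),
}


class PercentileReferenceProvider:
    """Percentile thresholds for MetS components, interpolated in age.

    Each accessor returns the threshold in the measured unit (cm, mmHg,
    mg/dL, or dimensionless for HOMA-IR).  Missing curves raise
    :class:`CoverageError` so a partially populated table cannot silently
    classify.
    """

    def __init__(self, curves: dict):
        self._curves = curves

    def _get(self, name: str, sex: Sex, age: float) -> float:
        curve = self._curves.get((Sex.parse(sex), name))
        if curve is None:
            raise CoverageError(f"reference table has no {name} curve for sex {sex}")
        return curve(age)

    def wc_p90(self, sex: Sex, age: float) -> float:
        return self._get("wc_p90", sex, age)

    def sbp_p90(self, sex: Sex, age: float) -> float:
        return self._get("sbp_p90", sex, age)

    def dbp_p90(self, sex: Sex, age: float) -> float:
        return self._get("dbp_p90", sex, age)

    def tg_p90(self, sex: Sex, age: float) -> float:
        return self._get("tg_p90", sex, age)

    def hdl_p10(self, sex: Sex, age: float) -> float:
        return self._get("hdl_p10", sex, age)

    def homa_p90(self, sex: Sex, age: float) -> float:
        return self._get("homa_p90", sex, age)

    def glucose_p90(self, sex: Sex, age: float) -> float:
        return self._get("glucose_p90", sex, age)


def load_reference_tables(path) -> tuple[TableBmiReference, PercentileReferenceProvider]:
    """Read the long-format reference CSV into the two lookup objects."""
    df = pd.read_csv(path)
    missing = {"sex", "age_years", "variable"} - set(df.columns)
    if missing:
        raise SchemaError(f"reference CSV missing columns: {sorted(missing)}")
    return reference_objects_from_frame(df)


def reference_objects_from_frame(
    df: pd.DataFrame,
) -> tuple[TableBmiReference, PercentileReferenceProvider]:
    bmi_curves: dict = {}
    pct_curves: dict = {}
    for (sex_str, variable), grp in df.groupby(["sex", "variable"]):
        sex = Sex.parse(sex_str)
        ages = grp["age_years"].to_numpy(dtype=float)
        if variable == "bmi":
            for param in ("L", "M", "S"):
                if param in grp.columns and grp[param].notna().all():
                    bmi_curves[(sex, param)] = _AgeCurve(
                        ages, grp[param].to_numpy(dtype=float), f"bmi/{param}/{sex.value}"
                    )
        else:
            for method, (var, col) in _PROVIDER_CURVES.items():
                if var == variable and col in grp.columns and grp[col].notna().all():
                    pct_curves[(sex, method)] = _AgeCurve(
                        ages, grp[col].to_numpy(dtype=float), f"{variable}/{col}/{sex.value}"
                    )
    for sex in Sex:
        for param in ("M", "S"):
            if (sex, param) not in bmi_curves:
                raise SchemaError(f"reference CSV lacks bmi {param} curve for {sex.value}")
    return TableBmiReference(bmi_curves), PercentileReferenceProvider(pct_curves)
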