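"""Cohort CSV reading and writing with row-level validation.

The cohort schema is one row per subject, fixed header, UTF-8, '.' decimal
separator::

    id, age_years, sex{F,M}, tanner, weight_kg, height_cm, waist_cm,
    fm_kg, ffm_kg, glucose_mgdl, insulin_uUml, hba1c_pct, tc_mgdl,
    hdl_mgdl, tg_mgdl, sbp_mmhg, dbp_mmhg, rx_lipid{0,1}, rx_bp{0,1},
    dx_igt_t2dm{0,1}

``tanner``, ``fm_kg``, ``ffm_kg`` and ``hba1c_pct`` may be empty (missing);
every other cell is required.  Invalid rows are rejected with a line-number
message, never coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import PedmetsError, SchemaError
from .indices import SubjectRecord

__all__ = ["COHORT_COLUMNS", "CohortData", "record_from_row", "read_cohort",
           "write_cohort", "records_to_frame"]

COHORT_COLUMNS = [
    "id", "age_years", "sex", "tanner", "weight_kg", "height_cm", "waist_cm",
    "fm_kg", "ffm_kg", "glucose_mgdl", "insulin_uUml", "hba1c_pct",
    "tc_mgdl", "hdl_mgdl", "tg_mgdl", "sbp_mmhg", "dbp_mmhg",
    "rx_lipid", "rx_bp", "dx_igt_t2dm",
]

_OPTIONAL = {"tanner", "fm_kg", "ffm_kg", "hba1c_pct"}
_FLAGS = {"rx_lipid", "rx_bp", "dx_igt_t2dm"}


@dataclass
class CohortData:
    """Validated cohort: typed records, the corresponding frame, and the
    messages for any rejected rows."""

    records: list[SubjectRecord]
    frame: pd.DataFrame
    errors: list[str]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _parse_float(row, name: str) -> float:
    v = row[name]
    if _is_missing(v):
        raise ValueError(f"missing value in required column '{name}'")
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable value {v!r} in column '{name}'") from None


def _parse_optional_float(row, name: str):
    v = row[name]
    if _is_missing(v):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable value {v!r} in column '{name}'") from None


def _parse_flag(row, name: str) -> bool:
    v = row[name]
    if _is_missing(v):
        raise ValueError(f"missing value in flag column '{name}'")
    s = str(v).strip()
    if s in ("0", "1"):
        return s == "1"
    raise ValueError(f"flag column '{name}' must be 0 or 1, got {v!r}")


def record_from_row(row) -> SubjectRecord:
    """Build a validated SubjectRecord from one schema row (mapping-like)."""
    tanner = _parse_optional_float(row, "tanner")
    if tanner is not None:
        if tanner != int(tanner):
            raise ValueError(f"tanner must be an integer 1-5, got {tanner!r}")
        tanner = int(tanner)
    return SubjectRecord(
        id=str(row["id"]),
        age=_parse_float(row, "age_years"),
        sex=str(row["sex"]),
        tanner=tanner,
        weight=_parse_float(row, "weight_kg"),
        height=_parse_float(row, "height_cm"),
        waist=_parse_float(row, "waist_cm"),
        fat_mass=_parse_optional_float(row, "fm_kg"),
        fat_free_mass=_parse_optional_float(row, "ffm_kg"),
        glucose=_parse_float(row, "glucose_mgdl"),
        insulin=_parse_float(row, "insulin_uUml"),
        hba1c=_parse_optional_float(row, "hba1c_pct"),
        total_chol=_parse_float(row, "tc_mgdl"),
        hdl=_parse_float(row, "hdl_mgdl"),
        tg=_parse_float(row, "tg_mgdl"),
        sbp=_parse_float(row, "sbp_mmhg"),
        dbp=_parse_float(row, "dbp_mmhg"),
        on_lipid_treatment=_parse_flag(row, "rx_lipid"),
        on_bp_treatment=_parse_flag(row, "rx_bp"),
        diagnosed_igt_t2dm=_parse_flag(row, "dx_igt_t2dm"),
    )


def validate_frame(df: pd.DataFrame) -> CohortData:
    """Validate a schema-shaped frame row by row (see read_cohort)."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {missing}")
    records: list[SubjectRecord] = []
    errors: list[str] = []
    keep_idx = []
    for pos, (idx, row) in enumerate(df.iterrows()):
        try:
            records.append(record_from_row(row))
            keep_idx.append(idx)
        except (ValueError, PedmetsError) as exc:
            # +2: header line plus 1-based numbering of a plain CSV file
            errors.append(f"line {pos + 2}: {exc}")
    return CohortData(records, df.loc[keep_idx, COHORT_COLUMNS].copy(), errors)


def read_cohort(path) -> CohortData:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` when the header is wrong; individual bad
    rows are dropped and reported in ``CohortData.errors`` with their line
    numbers.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str, "sex": str})
    except pd.errors.ParserError as exc:
        raise SchemaError(f"cannot parse cohort CSV {path}: {exc}") from exc
    return validate_frame(df)


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "age_years": r.age, "sex": r.sex.value,
            "tanner": r.tanner, "weight_kg": r.weight, "height_cm": r.height,
            "waist_cm": r.waist, "fm_kg": r.fat_mass, "ffm_kg": r.fat_free_mass,
            "glucose_mgdl": r.glucose, "insulin_uUml": r.insulin,
            "hba1c_pct": r.hba1c, "tc_mgdl": r.total_chol, "hdl_mgdl": r.hdl,
            "tg_mgdl": r.tg, "sbp_mmhg": r.sbp, "dbp_mmhg": r.dbp,
            "rx_lipid": int(r.on_lipid_treatment), "rx_bp": int(r.on_bp_treatment),
            "dx_igt_t2dm": int(r.diagnosed_igt_t2dm),
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort frame in the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {missing}")
    df[COHORT_COLUMNS].to_csv(path, index=False)
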