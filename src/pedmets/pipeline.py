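"""End-to-end analysis pipeline.

Reproduces the study sequence on a cohort table: box-plot outlier screen
(reported, never used to exclude anyone), index panel computation, MetS
classification, per-index diagnostic reports for the whole group and each
sex, a Spearman table of the TG/HDL-C ratio against the MetS components,
and an age-resolved cutoff trend per sex.  All artifacts are written with a
manifest echoing the seed and configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .errors import DegenerateInputError, PipelineStageError, RowValidationError
from .indices import INDEX_NAMES, compute_all_indices
from .io import read_cohort, record_from_row, validate_frame, write_cohort
from .mets import classify_weight_status, diagnose_mets
from .references import PercentileReferenceProvider, TableBmiReference, load_reference_tables

__all__ = ["RunConfig", "index_frame", "classify_frame", "spearman_table",
           "outlier_screen", "prevalence_block", "run_pipeline", "write_report"]

# Variables screened for outliers and correlated with TG/HDL-C
_SCREEN_VARS = ["age_years", "weight_kg", "height_cm", "waist_cm",
                "glucose_mgdl", "insulin_uUml", "tc_mgdl", "hdl_mgdl",
                "tg_mgdl", "sbp_mmhg", "dbp_mmhg"]
_SPEARMAN_VARS = [("bmi", "panel"), ("bmi_sds", "panel"),
                  ("glucose_mgdl", "cohort"), ("hdl_mgdl", "cohort"),
                  ("tg_mgdl", "cohort"), ("sbp_mmhg", "cohort"),
                  ("dbp_mmhg", "cohort")]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    cohort_path: str
    reference_path: str
    output_dir: str
    indices: tuple = INDEX_NAMES
    ci: str = "wald"
    correction: str = "yates"
    by_sex: bool = True
    trend_index: str = "tg_hdl"
    trend_window: float = 4.0
    trend_min_n: int = 10
    treated_lipids_double_count: bool = False
    vai_literal: bool = False
    strict_rows: bool = False
    seed: int = 0


def index_frame(df: pd.DataFrame, bmi_ref: TableBmiReference,
                *, vai_literal: bool = False) -> pd.DataFrame:
    """Per-subject index panel as a frame (id + 12 indices + HOMA-IR).

    Indices whose optional inputs are absent come out as NaN in the frame
    (the panel-level contract is None; NaN is the tabular encoding).
    """
    rows = []
    for _, row in df.iterrows():
        rec = record_from_row(row)
        panel = compute_all_indices(rec, bmi_ref, vai_literal=vai_literal)
        entry = {"id": rec.id}
        for name in INDEX_NAMES + ("homa_ir",):
            v = panel.get(name)
            entry[name] = np.nan if v is None else v
        rows.append(entry)
    return pd.DataFrame(rows)


def classify_frame(df: pd.DataFrame, panels: pd.DataFrame,
                   provider: PercentileReferenceProvider,
                   *, treated_lipids_double_count: bool = False) -> pd.DataFrame:
    """MetS classification per subject: criteria set, flags, diagnosis."""
    panels = panels.set_index("id") if "id" in panels.columns else panels
    rows = []
    for _, row in df.iterrows():
        rec = record_from_row(row)
        prow = panels.loc[rec.id]
        panel = _panel_stub(prow)
        res = diagnose_mets(rec, panel, provider,
                            treated_lipids_double_count=treated_lipids_double_count)
        rows.append({
            "id": rec.id,
            "criteria_set": res.criteria_set.value,
            "abdominal_obesity": int(res.abdominal_obesity),
            "bp_flag": int(res.bp_flag),
            "lipid_tg_flag": int(res.lipid_tg_flag),
            "lipid_hdl_flag": int(res.lipid_hdl_flag),
            "glucose_flag": int(res.glucose_flag),
            "n_components": res.n_components,
            "mets": int(res.mets),
            "weight_status": classify_weight_status(float(prow["bmi_sds"])),
        })
    return pd.DataFrame(rows)


class _PanelView:
    """Minimal panel adapter over a frame row (only fields the rules read)."""

    __slots__ = ("homa_ir",)

    def __init__(self, homa_ir: float):
        self.homa_ir = homa_ir


def _panel_stub(prow) -> _PanelView:
    return _PanelView(float(prow["homa_ir"]))


def outlier_screen(df: pd.DataFrame) -> dict[str, int]:
    """Box-plot outlier counts per screened variable (report only)."""
    out = {}
    for var in _SCREEN_VARS:
        x = pd.to_numeric(df[var], errors="coerce").dropna().to_numpy()
        out[var] = int(dx.tukey_outliers(x).sum()) if x.size >= 4 else 0
    return out


def prevalence_block(classified: pd.DataFrame, sexes: pd.Series,
                     correction: str) -> dict:
    """MetS prevalence overall, by sex and by weight status, with the 2x2
    chi-square comparisons (explicit continuity-correction choice)."""
    mets = classified["mets"].astype(bool)
    obese = classified["weight_status"] == "obese"
    female = (sexes == "F").to_numpy()

    def cell(mask) -> dict:
        k, n = int(mets[mask].sum()), int(mask.sum())
        return {"mets": k, "n": n,
                "percent": dx.prevalence_percent(k, n) if n else None}

    block = {
        "overall": cell(np.ones(len(mets), dtype=bool)),
        "female": cell(female),
        "male": cell(~female),
        "obese": cell(obese.to_numpy()),
        "non_obese": cell((~obese).to_numpy()),
        "obese_fraction_percent": dx.prevalence_percent(int(obese.sum()), len(obese)),
    }
    try:
        a = int((mets & female).sum())
        b = int((~mets & female).sum())
        c = int((mets & ~female).sum())
        d = int((~mets & ~female).sum())
        chi2, p = dx.chi2_2x2(a, b, c, d, correction)
        block["mets_by_sex_chi2"] = {"chi2": chi2, "p": p, "correction": correction}
    except DegenerateInputError:
        block["mets_by_sex_chi2"] = None
    try:
        a = int((mets & obese).sum())
        b = int((~mets & obese).sum())
        c = int((mets & ~obese).sum())
        d = int((~mets & ~obese).sum())
        chi2, p = dx.chi2_2x2(a, b, c, d, correction)
        block["mets_by_weight_chi2"] = {"chi2": chi2, "p": p, "correction": correction}
    except DegenerateInputError:
        block["mets_by_weight_chi2"] = None
    return block


def spearman_table(df: pd.DataFrame, panels: pd.DataFrame,
                   strata: dict[str, np.ndarray]) -> dict:
    """TG/HDL-C ratio vs MetS components: rho and p per stratum."""
    tg_hdl = panels["tg_hdl"].to_numpy(dtype=float)
    out: dict = {}
    for var, source in _SPEARMAN_VARS:
        series = (panels[var] if source == "panel" else df[var])
        x = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        out[var] = {}
        for stratum, mask in strata.items():
            sel = mask & np.isfinite(x) & np.isfinite(tg_hdl)
            try:
                rho, p = dx.spearman_rho(tg_hdl[sel], x[sel])
                out[var][stratum] = {"rho": rho, "p": p, "n": int(sel.sum())}
            except DegenerateInputError:
                out[var][stratum] = None
    return out


def _report_to_dict(report: dx.DiagnosticReport) -> dict:
    d = {
        "index": report.index, "n": report.n, "n_pos": report.n_pos,
        "auc": report.auc.as_tuple(), "cutoff": report.cutoff,
        "youden": report.youden, "counts": report.counts,
    }
    for name in ("sens", "spec", "ppv", "npv", "plr", "nlr"):
        v = report.metrics[name]
        d[name] = v.as_tuple() if v is not None else None
    return d


def _evaluate_all(panels: pd.DataFrame, labels: np.ndarray,
                  strata: dict[str, np.ndarray], indices, ci: str
                  ) -> tuple[dict, list[dict]]:
    reports: dict = {}
    roc_rows: list[dict] = []
    for name in indices:
        scores = panels[name].to_numpy(dtype=float)
        reports[name] = {}
        for stratum, mask in strata.items():
            sel = mask & np.isfinite(scores)
            try:
                cohort = dx.ScoredCohort(scores[sel], labels[sel])
                rep = dx.evaluate_index(cohort, index=name, ci=ci)
            except DegenerateInputError as exc:
                reports[name][stratum] = {"undefined": str(exc)}
                continue
            reports[name][stratum] = _report_to_dict(rep)
            for t, sens, fpr in rep.roc:
                roc_rows.append({"index": name, "stratum": stratum,
                                 "threshold": t, "sensitivity": sens,
                                 "fpr": fpr})
    return reports, roc_rows


def run_pipeline(config: RunConfig,
                 cohort: Optional[pd.DataFrame] = None) -> dict:
    """Run the full analysis; returns the JSON-serialisable bundle.

    ``cohort`` may be passed directly (already schema-shaped) to skip the
    file read; otherwise ``config.cohort_path`` is loaded.
    """
    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrap

    if cohort is None:
        data = stage("read_cohort")(read_cohort, config.cohort_path)
    else:
        data = stage("validate_cohort")(validate_frame, cohort)
    if config.strict_rows and data.errors:
        raise PipelineStageError("read_cohort", RowValidationError(data.errors))
    df = data.frame.reset_index(drop=True)

    bmi_ref, provider = stage("read_references")(load_reference_tables,
                                                 config.reference_path)
    outliers = stage("outlier_screen")(outlier_screen, df)
    panels = stage("indices")(index_frame, df, bmi_ref,
                              vai_literal=config.vai_literal)
    classified = stage("classify")(
        classify_frame, df, panels, provider,
        treated_lipids_double_count=config.treated_lipids_double_count)
    labels = classified["mets"].astype(bool).to_numpy()
    sexes = df["sex"].astype(str).to_numpy()
    ages = pd.to_numeric(df["age_years"]).to_numpy(dtype=float)

    strata: dict[str, np.ndarray] = {"all": np.ones(len(df), dtype=bool)}
    if config.by_sex:
        strata["F"] = sexes == "F"
        strata["M"] = sexes == "M"

    prevalence = stage("prevalence")(prevalence_block, classified,
                                     df["sex"].astype(str), config.correction)
    reports, roc_rows = stage("evaluate")(_evaluate_all, panels, labels,
                                          strata, config.indices, config.ci)
    spearman = stage("spearman")(spearman_table, df, panels, strata)

    trend: dict = {}
    trend_scores = panels[config.trend_index].to_numpy(dtype=float)
    for sex in ("F", "M"):
        try:
            pts = stage("cutoff_trend")(
                dx.cutoff_trend,
                dx.ScoredCohort(trend_scores, labels, sex=sexes, age=ages),
                sex, window=config.trend_window, min_n=config.trend_min_n)
        except PipelineStageError:
            pts = []
        trend[sex] = [{"age": a, "cutoff": c} for a, c in pts]

    return {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "n_subjects": int(len(df)),
        "row_errors": data.errors,
        "outliers": outliers,
        "prevalence": prevalence,
        "reports": reports,
        "spearman": spearman,
        "cutoff_trend": {"index": config.trend_index, "by_sex": trend},
        "_frames": {"cohort": df, "panels": panels, "classified": classified,
                    "roc": pd.DataFrame(roc_rows)},
    }


def write_report(bundle: dict, out_dir) -> list[str]:
    """Write the bundle as JSON + CSV artifacts with a manifest.

    Returns the list of files written (relative names).  JSON keys are
    sorted for diffability; non-finite numbers are serialised as null.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = bundle.get("_frames", {})
    files = []

    write_cohort(frames["cohort"], out / "cohort.csv")
    files.append("cohort.csv")
    frames["panels"].to_csv(out / "indices.csv", index=False)
    files.append("indices.csv")
    frames["classified"].to_csv(out / "classification.csv", index=False)
    files.append("classification.csv")
    if len(frames["roc"]):
        frames["roc"].to_csv(out / "roc_points.csv", index=False)
        files.append("roc_points.csv")

    payload = {k: v for k, v in bundle.items() if not k.startswith("_")}
    payload["manifest"] = sorted(files + ["report.json"])

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(clean(payload), fh, sort_keys=True, indent=2, default=default)
        fh.write("\n")
    files.append("report.json")
    return sorted(files)
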