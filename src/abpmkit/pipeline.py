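"""End-to-end orchestration: readings + cohort table in, report out.

The pipeline runs parse → validate → summarise → classify → compare →
regress → ROC.  Subjects whose recording fails the validity rules (or
whose organ assessments are all indeterminate) are excluded with a
logged reason and listed in the run manifest; the remaining subjects
flow through unchanged.  Output is a directory of CSV tables plus a
JSON manifest (seed, semantic config hash, versions), deterministic
for a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import abpmkit
from abpmkit.config import RunConfig
from abpmkit.hmod import Demographics, EchoMeasurements, HMODStatus, LabPanel, hmod_composite
from abpmkit.recording import ABPMRecording, arv, aasi, ppi, summarize_windows, validate_recording
from abpmkit.stats import (
    SeparationError,
    collinearity_diagnostics,
    compare_groups,
    fit_multivariable,
    fit_univariable,
    roc_analysis,
    select_predictors,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisReport",
    "load_readings",
    "summarize_cohort",
    "classify_cohort",
    "organ_frequency",
    "run_pipeline",
]

_ECHO_FIELDS = (
    "lved",
    "ivst",
    "pwt",
    "lvef",
    "e_wave",
    "a_wave",
    "e_a_ratio",
    "septal_e_prime",
    "lateral_e_prime",
    "e_over_e_prime",
    "lavi",
    "trv",
    "dt",
)


@dataclass
class AnalysisReport:
    """All pipeline outputs, each table keyed by subject id or variable."""

    validity: pd.DataFrame
    summaries: pd.DataFrame
    hmod_status: pd.DataFrame
    hmod_frequency: pd.DataFrame
    comparisons: pd.DataFrame
    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    roc: pd.DataFrame
    diagnostics: dict
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "validity",
            "summaries",
            "hmod_status",
            "hmod_frequency",
            "comparisons",
            "univariable",
            "multivariable",
            "roc",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump({**self.manifest, "diagnostics": self.diagnostics}, fh, indent=2, default=str)
        return out


def load_readings(path: str | Path, config: RunConfig | None = None) -> dict[str, ABPMRecording]:
    """Read a combined readings CSV (column ``subject_id``) into recordings.

    Subjects whose rows cannot form a legal recording are skipped with
    a logged error; the caller sees them as absent.
    """
    cfg = (config or RunConfig()).window_config()
    df = pd.read_csv(path)
    required = {"subject_id", "timestamp", "sbp", "dbp"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    recordings = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        try:
            recordings[str(sid)] = ABPMRecording(str(sid), sub.drop(columns="subject_id"), cfg)
        except ValueError as exc:
            logger.error("skipping subject %s: %s", sid, exc)
    return recordings


def summarize_cohort(
    recordings: dict[str, ABPMRecording], config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Validity report and ABPM summary per subject; exclusions listed."""
    config = config or RunConfig()
    thresholds = config.thresholds()
    validity_rows, summary_rows, excluded = [], [], []
    for sid, rec in recordings.items():
        report = validate_recording(rec)
        validity_rows.append({"subject_id": sid, **report.to_dict()})
        if not report.passes:
            excluded.append({"subject_id": sid, "reason": "failed ABPM validity rules"})
            logger.info("subject %s excluded: validity %s", sid, report.to_dict())
            continue
        summary = summarize_windows(rec, thresholds)
        row = summary.to_dict()
        if config.arv_time_weighted:
            row["arv_sbp"] = arv(rec, "sbp", time_weighted=True)
            row["arv_dbp"] = arv(rec, "dbp", time_weighted=True)
        if not config.ppi_per_reading:
            row["ppi"] = ppi(rec, per_reading=False)
        summary_rows.append({"subject_id": sid, **row})
    return pd.DataFrame(validity_rows), pd.DataFrame(summary_rows), excluded


def _status_for_row(row: pd.Series, config: RunConfig) -> HMODStatus:
    echo = EchoMeasurements(
        **{f: (float(row[f]) if f in row and pd.notna(row[f]) else None) for f in _ECHO_FIELDS}
    )
    demo = Demographics(
        age=float(row["age"]),
        sex=str(row["sex"]),
        height=float(row["height"]) if pd.notna(row.get("height")) else None,
        weight=float(row["weight"]) if pd.notna(row.get("weight")) else None,
        smoking=bool(row.get("smoking", False)),
    )
    labs = LabPanel(
        serum_creatinine=float(row["serum_creatinine"]) if pd.notna(row.get("serum_creatinine")) else None,
        urine_albumin_creatinine_ratio=(
            float(row["urine_albumin_creatinine_ratio"])
            if pd.notna(row.get("urine_albumin_creatinine_ratio"))
            else None
        ),
    )
    fundus = bool(row["fundoscopy_flag"]) if pd.notna(row.get("fundoscopy_flag")) else None
    return hmod_composite(
        echo, demo, labs, fundus, bsa_formula=config.bsa_formula, egfr_version=config.egfr_version
    )


def classify_cohort(
    cohort: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject HMOD status plus the organ-combination frequency table."""
    config = config or RunConfig()
    rows = []
    for _, row in cohort.iterrows():
        status = _status_for_row(row, config)
        rows.append(
            {
                "subject_id": row["subject_id"],
                "cardiac": status.cardiac,
                "cardiac_basis": status.cardiac_basis,
                "retinal": status.retinal,
                "renal": status.renal,
                "renal_basis": status.renal_basis,
                "diastolic_grade": status.diastolic_grade,
                "hmod": int(status.hmod),
                "organ_combination": status.organ_combination(),
            }
        )
    status_df = pd.DataFrame(rows)
    return status_df, organ_frequency(status_df)


def organ_frequency(status_df: pd.DataFrame) -> pd.DataFrame:
    """Frequency table of organ-damage combinations among damaged subjects."""
    damaged = status_df[status_df["hmod"] == 1]
    counts = damaged["organ_combination"].value_counts()
    return (
        pd.DataFrame(
            {
                "organ_combination": counts.index,
                "count": counts.to_numpy(),
                "percent_of_hmod": 100.0 * counts.to_numpy() / max(len(damaged), 1),
            }
        )
        .sort_values("count", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def run_pipeline(
    config: RunConfig,
    cohort_path: str | Path,
    readings_path: str | Path,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Execute the full analysis and optionally write the report directory.

    The outcome for the comparison/regression/ROC stages is the
    rule-based HMOD classification computed here from the cohort table
    (column ``hmod_classified``); the per-subject ABPM indices come
    from the recordings.
    """
    cohort = pd.read_csv(cohort_path)
    if "subject_id" not in cohort.columns:
        raise ValueError(f"{cohort_path}: cohort table needs a subject_id column")
    cohort["subject_id"] = cohort["subject_id"].astype(str)
    recordings = load_readings(readings_path, config)

    validity, summaries, excluded = summarize_cohort(recordings, config)
    for sid in cohort["subject_id"]:
        if sid not in recordings:
            excluded.append({"subject_id": sid, "reason": "no parseable recording"})
    status_df, freq = classify_cohort(cohort, config)

    analysis = (
        cohort.merge(summaries, on="subject_id", how="inner")
        .merge(status_df[["subject_id", "hmod"]].rename(columns={"hmod": "hmod_classified"}),
               on="subject_id", how="inner")
    )
    if analysis.empty:
        raise ValueError("no subject survived validity filtering; nothing to analyse")
    outcome = "hmod_classified"
    if analysis[outcome].nunique() < 2:
        raise ValueError("classified outcome has a single level; comparison impossible")

    compare_vars = [
        v for v in (
            "age", "sex", "bmi", "smoking", "hemoglobin", "hba1c",
            "serum_creatinine", "urine_albumin_creatinine_ratio",
            "lved", "ivst", "pwt", "lvef", "e_a_ratio", "trv", "lavi",
            "mean_sbp_24h", "mean_dbp_24h", "mean_sbp_day", "mean_dbp_day",
            "mean_sbp_night", "mean_dbp_night",
            "load_sbp_24h", "load_dbp_24h",
            "nocturnal_sbp_reduction", "nocturnal_dbp_reduction",
            "arv_sbp", "arv_dbp", "aasi", "ppi",
        )
        if v in analysis.columns
    ]
    comparisons = pd.DataFrame(
        [c.__dict__ for c in compare_groups(analysis, outcome, compare_vars)]
    )

    candidates = [v for v in config.candidate_predictors if v in analysis.columns]
    uni_rows, uni_p = [], []
    for var in candidates:
        try:
            res = fit_univariable(analysis, outcome, var)
        except (SeparationError, ValueError) as exc:
            logger.warning("univariable fit for %s skipped: %s", var, exc)
            continue
        row = res.table.iloc[0]
        uni_rows.append(row)
        uni_p.append((var, float(row["p_value"])))
    univariable = pd.DataFrame(uni_rows).reset_index(drop=True)

    selected = select_predictors(uni_p, config.forced_clinical, config.p_screen)
    try:
        multi = fit_multivariable(analysis, outcome, selected, hl_groups=config.hl_groups)
        multivariable = multi.table.copy()
        model_info = {
            "hosmer_lemeshow_p": multi.hosmer_lemeshow_p,
            "nagelkerke_r2": multi.nagelkerke_r2,
            "included_variables": list(multi.included_variables),
            "n": multi.n,
        }
    except SeparationError as exc:
        logger.warning("multivariable model abandoned: %s", exc)
        multivariable = pd.DataFrame(
            columns=["variable", "odds_ratio", "ci_low", "ci_high", "p_value"]
        )
        model_info = {"error": str(exc), "included_variables": selected}

    diagnostics = {}
    if len(selected) >= 2:
        try:
            diag = collinearity_diagnostics(analysis, selected, outcome)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("collinearity diagnostics failed: %s", exc)
            diag = None
        diagnostics = {} if diag is None else {
            "pearson_r_max": diag.pearson_r_max,
            "tolerance_min": diag.tolerance_min,
            "vif_max": diag.vif_max,
            "condition_number": diag.condition_number,
            "std_residual_range": diag.std_residual_range,
            "cooks_distance_max": diag.cooks_distance_max,
            "flags": diag.flags,
        }

    roc_rows = []
    for var in config.roc_variables:
        if var not in analysis.columns:
            continue
        r = roc_analysis(analysis[var].to_numpy(), analysis[outcome].to_numpy())
        roc_rows.append({"variable": var, **r.__dict__})
    roc = pd.DataFrame(roc_rows)

    manifest = {
        "seed": config.seed,
        "config_hash": config.semantic_hash(),
        "abpmkit_version": abpmkit.__version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "n_subjects_input": int(len(cohort)),
        "n_subjects_analysed": int(len(analysis)),
        "excluded": excluded,
        "model": model_info,
    }
    report = AnalysisReport(
        validity=validity,
        summaries=summaries,
        hmod_status=status_df,
        hmod_frequency=freq,
        comparisons=comparisons,
        univariable=univariable,
        multivariable=multivariable,
        roc=roc,
        diagnostics=diagnostics,
        manifest=manifest,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
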