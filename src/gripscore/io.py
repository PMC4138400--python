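"""On-disk formats: trial CSVs, cohort manifests, reports and plots.

Formats are deliberately plain: one CSV per trial with the header
``t_s,target_pct_mvc,response_pct_mvc``; a JSON manifest tying subjects,
visits, trial files, survey answers and (for simulated cohorts) the latent
ground truth together; and a versioned JSON report whose schema is published
from the pydantic model in this module.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ValidationError

from .analysis import CohortResults
from .exceptions import FormatError, InvalidDataError
from .simulate import CohortDataset, SimulationConfig, SubjectState
from .stats import AgreementResult
from .surveys import ODIResponse
from .tracking import TrackingTrial, visit_score

logger = logging.getLogger("gripscore")

TRIAL_HEADER = ["t_s", "target_pct_mvc", "response_pct_mvc"]
MANIFEST_NAME = "manifest.json"


# --------------------------------------------------------------------------
# trial CSVs
# --------------------------------------------------------------------------

def write_trial_csv(trial: TrackingTrial, path: str | Path) -> None:
    """Write one trial as CSV with full float precision."""
    df = pd.DataFrame(
        {
            "t_s": trial.sample_times,
            "target_pct_mvc": trial.target,
            "response_pct_mvc": trial.response,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trial_csv(
    path: str | Path, subject_id: str = "", visit_id: str = "", trial_index: int = 0
) -> TrackingTrial:
    """Read and validate one trial CSV.

    Raises :class:`FormatError` naming the missing column, or
    :class:`InvalidDataError` with the offending row for non-numeric cells or
    a non-increasing time grid.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trial file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in TRIAL_HEADER:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    for col in TRIAL_HEADER:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise InvalidDataError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"'{col}', data row {row + 1}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().values)[0])
            raise InvalidDataError(f"{path}: empty cell in column '{col}', data row {row + 1}")
        df[col] = numeric
    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidDataError(f"{path}: t_s must be strictly increasing")
    duration = float(t[-1] - t[0]) + float(np.median(np.diff(t)))
    return TrackingTrial(
        sample_times=t,
        target=df["target_pct_mvc"].to_numpy(dtype=float),
        response=df["response_pct_mvc"].to_numpy(dtype=float),
        duration=duration,
        subject_id=subject_id,
        visit_id=visit_id,
        trial_index=trial_index,
    )


# --------------------------------------------------------------------------
# cohort directory (trials + manifest)
# --------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort as a directory of trial CSVs plus a JSON manifest."""
    out_dir = Path(out_dir)
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(parents=True, exist_ok=True)

    subjects_json = []
    for s in dataset.subjects:
        visits_json = []
        for v in dataset.visits_of(s.subject_id):
            files = []
            for trial in dataset.trials.get((s.subject_id, v.visit_id), ()):
                fname = f"{s.subject_id}_{v.visit_id}_{trial.trial_index}.csv"
                write_trial_csv(trial, trial_dir / fname)
                files.append(f"trials/{fname}")
            odi = dataset.odi_of(s.subject_id, v.visit_id)
            visits_json.append(
                {
                    "visit_id": v.visit_id,
                    "timepoint_label": v.timepoint_label,
                    "trial_files": files,
                    "odi_items": list(odi.item_scores) if odi is not None else None,
                }
            )
        ground_truth = dataclasses.asdict(s)
        subjects_json.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "visits": visits_json,
                "ground_truth": ground_truth,
            }
        )
    manifest = {
        "format_version": "1.0",
        "seed": dataset.seed,
        "config": dataset.config.to_dict() if dataset.config is not None else None,
        "subjects": subjects_json,
    }
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_cohort(in_dir: str | Path) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"no {MANIFEST_NAME} in {in_dir}")
    manifest = json.loads(manifest_path.read_text())
    config = (
        SimulationConfig.from_dict(manifest["config"])
        if manifest.get("config")
        else None
    )

    subjects, visits, odi = [], [], []
    trials: dict[tuple[str, str], tuple[TrackingTrial, ...]] = {}
    for subj in manifest["subjects"]:
        sid = subj["subject_id"]
        gt = subj.get("ground_truth")
        if gt is not None:
            subjects.append(SubjectState(**gt))
        else:
            subjects.append(
                SubjectState(
                    subject_id=sid,
                    group=subj["group"],
                    theta=0.0,
                    mvc=0.0,
                    learning_rate=1.0,
                    motor_delay=0.0,
                )
            )
        for v in subj["visits"]:
            vid = v["visit_id"]
            vtrials = tuple(
                read_trial_csv(in_dir / f, subject_id=sid, visit_id=vid, trial_index=k)
                for k, f in enumerate(v["trial_files"])
            )
            if vtrials:
                trials[(sid, vid)] = vtrials
                visits.append(visit_score(vtrials))
            if v.get("odi_items") is not None:
                items = tuple(None if x is None else int(x) for x in v["odi_items"])
                odi.append(ODIResponse(items, subject_id=sid, visit_id=vid))
    return CohortDataset(
        subjects=tuple(subjects),
        visits=tuple(visits),
        trials=trials,
        odi=tuple(odi),
        config=config,
        seed=manifest.get("seed"),
    )


# --------------------------------------------------------------------------
# report: pydantic model, JSON, schema, CSV tables
# --------------------------------------------------------------------------

class CorrelationBlock(BaseModel):
    r: float
    p_value: float
    n: int


class GroupScoreBlock(BaseModel):
    label: str
    mean: float
    sd: float
    n: int


class ImprovementBlock(BaseModel):
    mean: float
    sd: float
    n: int
    p_vs_control: Optional[float] = None


class CorrelationSection(BaseModel):
    all: Optional[CorrelationBlock] = None
    outliers: list[list[str]] = []
    screened: Optional[CorrelationBlock] = None


class AgreementBlock(BaseModel):
    bias: float
    bias_ci: list[float]
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int
    direction: str


class ImprovementCorrelationSection(BaseModel):
    all: Optional[CorrelationBlock] = None
    screened: Optional[CorrelationBlock] = None


class AnalysisReport(BaseModel):
    """The versioned on-disk report; its JSON Schema is the published format."""

    schema_version: str
    n_control: int
    n_patient: int
    group_scores: list[GroupScoreBlock]
    functional_status: dict[str, str]
    improvements: dict[str, ImprovementBlock]
    correlation: CorrelationSection
    agreement: Optional[AgreementBlock] = None
    improvement_correlation: ImprovementCorrelationSection


def report_json_schema() -> dict:
    """The JSON Schema the report files conform to."""
    return AnalysisReport.model_json_schema()


def write_report(results: CohortResults, path: str | Path) -> AnalysisReport:
    """Validate results against the schema and write the report JSON."""
    report = AnalysisReport.model_validate(results.to_report())
    Path(path).write_text(report.model_dump_json(indent=2))
    return report


def read_report(path: str | Path) -> AnalysisReport:
    try:
        return AnalysisReport.model_validate_json(Path(path).read_text())
    except ValidationError as exc:
        raise FormatError(f"{path}: report does not match schema: {exc}") from exc


def write_report_tables(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Render the report as flat CSV tables (two-decimal style)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    scores = pd.DataFrame([g.model_dump() for g in report.group_scores])
    p = out_dir / "group_scores.csv"
    scores.round({"mean": 2, "sd": 2}).to_csv(p, index=False)
    written.append(p)

    rows = []
    for label, rec in report.improvements.items():
        rows.append(
            {
                "group": label,
                "pct_improvement_mean": round(100 * rec.mean, 2),
                "pct_improvement_sd": round(100 * rec.sd, 2),
                "n": rec.n,
                "p_vs_control": rec.p_vs_control,
            }
        )
    p = out_dir / "improvement.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)

    rows = []
    for name, block in (
        ("mae_vs_odi_all", report.correlation.all),
        ("mae_vs_odi_screened", report.correlation.screened),
        ("improvement_all", report.improvement_correlation.all),
        ("improvement_screened", report.improvement_correlation.screened),
    ):
        if block is not None:
            rows.append({"comparison": name, "r": round(block.r, 3), "p_value": block.p_value, "n": block.n})
    p = out_dir / "correlation.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)
    return written


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------

def plot_bland_altman(agreement: AgreementResult, path: str | Path) -> None:
    """Mean-vs-difference agreement plot with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(agreement.means, agreement.diffs, s=24, alpha=0.8)
    ax.axhline(agreement.bias, color="k", lw=1.2, label=f"bias {agreement.bias:.2f}")
    for y, lbl in ((agreement.loa_upper, "upper LoA"), (agreement.loa_lower, "lower LoA")):
        ax.axhline(y, color="gray", lw=1, ls="--", label=f"{lbl} {y:.2f}")
    ax.set_xlabel("mean of measures")
    ax.set_ylabel(f"difference ({agreement.direction})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mae_odi_scatter(results: CohortResults, path: str | Path) -> None:
    """Scatter of tracking MAE (fraction) against ODI with the OLS line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if results.paired is None:
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    flagged = {f"{s}/{v}" for s, v in results.outlier_subjects}
    is_out = np.array([sid in flagged for sid in results.paired.subject_ids])
    ax.scatter(
        results.paired.odi[~is_out], results.paired.mae_fraction[~is_out], s=24, alpha=0.8
    )
    if is_out.any():
        ax.scatter(
            results.paired.odi[is_out],
            results.paired.mae_fraction[is_out],
            s=40,
            marker="x",
            color="crimson",
            label="Cook's-distance outlier",
        )
        ax.legend(loc="best", fontsize=8)
    if results.regression is not None:
        xs = np.linspace(results.paired.odi.min(), results.paired.odi.max(), 50)
        ax.plot(
            xs,
            results.regression.intercept + results.regression.slope * xs,
            color="k",
            lw=1,
        )
    ax.set_xlabel("ODI index")
    ax.set_ylabel("tracking MAE (fraction of MVC)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
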