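"""End-to-end orchestration: simulate -> preprocess -> metrics -> reliability
-> validity, with exclusion logging and report artifacts.

Per recording: the last 60 s of a trial is selected, beats are detected
and corrected, the < 5%-corrected quality gate is applied to the
analyzed segment, and the vm-HRV metric set is computed.  Recordings
failing any stage are excluded with a machine-readable reason, never
imputed.  The reliability grid and validity verdicts are then assembled
per metric over the quality-passed complete cases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hrv_metrics as hm
from .errors import UndefinedMetricError, VmHrvError
from .preprocess import DetrendConfig, correct_beats, detect_artifacts, quality_gate
from .reliability import reliability_frame, reliability_report
from .rr_ingest import RRSeries, SessionTable, read_rr_text, segment_last
from .synthetic_data import CohortConfig, GroundTruth, generate_cohort
from .validity import validity_frame, validity_report

logger = logging.getLogger("vmhrv")

__all__ = ["PipelineConfig", "simulate_cohort", "analyze_cohort", "render_report"]

ANALYSIS_METRICS = ["mrr_ms", "rmssd_ms", "hf_ms2", "hf_nu", "sd1_ms", "pns_index"]


@dataclass
class PipelineConfig:
    """Analysis settings; numeric choices live here, not in CLI flags."""

    window_s: float = 60.0  # on-task analysis window (last n seconds)
    gate_max_fraction: float = 0.05
    alpha: float = 0.05  # two-sided significance level
    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    bands: hm.SpectralBands = field(default_factory=hm.SpectralBands)
    normals: hm.PnsNormals = field(default_factory=hm.PnsNormals)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def simulate_cohort(cfg: CohortConfig, out_dir, force: bool = False):
    """Write a synthetic cohort (RR files + session CSV + ground truth)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating cohort: n=%d seed=%d", cfg.n_subjects, cfg.seed)
    table, truth, series = generate_cohort(cfg, out_dir=out, signals=True)
    logger.info("wrote %d recordings to %s", len(series), out)
    return table, truth


def _load_series(cohort_dir: Path, key: str) -> RRSeries:
    return read_rr_text(cohort_dir / "rr" / (key.replace("|", "_") + ".txt"))


def process_recording(
    series: RRSeries, cfg: PipelineConfig, *, is_rest: bool = False
) -> hm.HRVMetrics:
    """Window -> correct -> gate -> metrics for one recording.

    Raises a package error when the recording is unusable; the caller
    records the exclusion.
    """
    seg = series if is_rest else segment_last(series, cfg.window_s)
    report = detect_artifacts(seg)
    if not quality_gate(report, cfg.gate_max_fraction):
        raise UndefinedMetricError(
            f"quality gate failed: {report.fraction_corrected:.1%} beats corrected"
        )
    correct_beats(seg, report)
    return hm.compute_all(
        seg, cfg.detrend, cfg.bands, cfg.normals, report=report
    )


def analyze_cohort(
    cohort_dir=None,
    cfg: PipelineConfig | None = None,
    out_dir=None,
    table: SessionTable | None = None,
    series_map: dict | None = None,
) -> dict:
    """Run the full analysis; returns a dict of DataFrames and the exclusion log.

    Input is either ``cohort_dir`` (a directory written by
    :func:`simulate_cohort`) or an in-memory ``table`` + ``series_map``.
    """
    cfg = cfg or PipelineConfig()
    if table is None:
        cohort_dir = Path(cohort_dir)
        table = SessionTable.from_csv(cohort_dir / "sessions.csv")
        if len(table) == 0:
            raise VmHrvError(f"empty cohort in {cohort_dir}")

    exclusions: list[dict] = []
    df = table.df.copy()  # never mutate the caller's table
    needs_metrics = df["mrr_ms"].isna().all()
    if needs_metrics:
        logger.info("computing metrics for %d recordings", len(df))
        for i, row in df.iterrows():
            key = GroundTruth.key(
                row["subject_id"], row["phase"], row["game"], row["level"],
                row["timepoint"],
            )
            try:
                if series_map is not None:
                    ser = series_map[key]
                elif cohort_dir is not None:
                    ser = _load_series(cohort_dir, key)
                else:
                    raise VmHrvError("no signal source for metric computation")
                metrics = process_recording(ser, cfg)
            except (VmHrvError, FileNotFoundError, KeyError) as exc:
                exclusions.append({"key": key, "reason": f"{type(exc).__name__}: {exc}"})
                df.loc[i, "quality_pass"] = False
                continue
            for col, val in metrics.as_dict().items():
                df.loc[i, col] = val
            df.loc[i, "quality_pass"] = True
    else:
        # summary-mode tables carry latent metrics already
        df["quality_pass"] = df["quality_pass"].fillna(True)
    table = SessionTable(df)
    df = table.df

    rel_frames, val_frames = [], []
    per_metric_iccs: dict = {}
    for metric in ANALYSIS_METRICS:
        if df[metric].isna().all():
            continue
        rel = reliability_report(table, metric, alpha=cfg.alpha)
        rel_frames.append(reliability_frame(rel))
        iccs: dict = {}
        for r in rel:
            iccs.setdefault((r.phase, r.game), {})[r.level] = r.icc
        per_metric_iccs[metric] = iccs
        val = validity_report(table, metric, iccs, alpha=cfg.alpha)
        val_frames.append(validity_frame(val))
    rel_df = pd.concat(rel_frames, ignore_index=True) if rel_frames else pd.DataFrame()
    val_df = pd.concat(val_frames, ignore_index=True) if val_frames else pd.DataFrame()

    summary = _summarize(rel_df, val_df)
    out = {
        "sessions": df,
        "reliability": rel_df,
        "validity": val_df,
        "exclusions": exclusions,
        "summary": summary,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "metrics.csv", index=False)
        rel_df.to_csv(out_dir / "reliability.csv", index=False)
        val_df.to_csv(out_dir / "validity.csv", index=False)
        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump(exclusions, fh, indent=1)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        logger.info(
            "analysis complete: %d conditions, %d exclusions -> %s",
            len(rel_df), len(exclusions), out_dir,
        )
    return out


def _summarize(rel_df: pd.DataFrame, val_df: pd.DataFrame) -> dict:
    summary: dict = {"metrics": {}}
    if len(rel_df):
        for metric, grp in rel_df[rel_df["estimable"] == True].groupby("metric"):  # noqa: E712
            entry = {
                "mean_icc": float(grp["icc"].mean()),
                "icc_range": [float(grp["icc"].min()), float(grp["icc"].max())],
                "mean_sem_pct": float(grp["sem_pct"].mean()),
                "mean_sdd_pct": float(grp["sdd_pct"].mean()),
                "n_conditions": int(len(grp)),
            }
            summary["metrics"][metric] = entry
    if len(val_df):
        for metric, grp in val_df.groupby("metric"):
            e = summary["metrics"].setdefault(metric, {})
            e["eligible_conditions"] = int(
                grp.drop_duplicates(["phase", "game"])["eligible"].sum()
            )
            sig = grp[(grp["comparison"] != "") & (grp["p_adj"] <= 0.05)]
            e["significant_pairwise"] = int(len(sig))
            if len(sig):
                e["mean_r"] = float(sig["r"].mean())
    return summary


def render_report(out_dir) -> str:
    """Human-readable markdown summary of an analysis directory."""
    out_dir = Path(out_dir)
    summ_path = out_dir / "summary.json"
    if not summ_path.exists():
        raise FileNotFoundError(f"no summary.json in {out_dir}; run analyze first")
    with open(summ_path) as fh:
        summary = json.load(fh)
    lines = ["# vm-HRV reliability & validity summary", ""]
    if not summary.get("metrics"):
        lines.append("No estimable conditions.")
    for metric, e in summary.get("metrics", {}).items():
        lines.append(f"## {metric}")
        if "mean_icc" in e:
            lines.append(
                f"- mean ICC(3,1) = {e['mean_icc']:.3f} "
                f"(range {e['icc_range'][0]:.3f} to {e['icc_range'][1]:.3f}) "
                f"over {e['n_conditions']} conditions"
            )
            lines.append(
                f"- mean SEM% = {e['mean_sem_pct']:.1f}%, "
                f"mean SDD% = {e['mean_sdd_pct']:.1f}%"
            )
        if "eligible_conditions" in e:
            verdict = (
                "valid at group level"
                if e.get("significant_pairwise", 0) > 0
                else "no significant level differences"
            )
            lines.append(
                f"- eligible in {e['eligible_conditions']} game(s); "
                f"{e['significant_pairwise']} significant pairwise contrasts "
                f"-> {verdict}"
            )
        lines.append("")
    text = "\n".join(lines)
    with open(out_dir / "report.md", "w") as fh:
        fh.write(text)
    return text
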