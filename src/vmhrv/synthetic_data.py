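"""Ground-truth cohort generator for the full analysis chain.

Emulates the statistical structure the reliability/validity analysis
assumes, with every latent quantity serialized as ground truth:

* subject-specific baseline mean RR with between-subject variance;
* a test-retest correlation tuned analytically to a target ICC by
  splitting variance between the subject latent and occasion noise
  (sigma_occ = sigma_between * sqrt((1 - icc)/icc));
* monotone demand-level effects on mean RR (vagal withdrawal shortens
  RR) and on the amplitude of the ~0.25 Hz respiratory oscillation;
* a slower 0.1 Hz oscillation, a slow trend, white beat-to-beat noise;
* injectable missed/extra/ectopic beat artifacts with truth indices.

Two cohort modes: full signal synthesis (an R-R series per recording)
and a summary mode that emits the latent condition-level mean RR values
directly — the latter keeps replicate-heavy parameter-recovery studies
cheap while preserving the exact analytic ICC control.

The respiratory modulation is a deterministic sinusoid rather than an
integral-pulse-frequency model so band powers have closed forms
(A^2 / 2) for oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .rr_ingest import RRSeries, SessionTable, write_rr_text

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_rr",
    "generate_cohort",
    "inject_artifacts",
]

DEFAULT_LEVEL_EFFECT = {"easy": 0.0, "challenging": -60.0, "excessive": -120.0}
DEFAULT_HF_AMP = {"easy": 40.0, "challenging": 30.0, "excessive": 20.0}
DEFAULT_TLX_MEAN = {"easy": 6.0, "challenging": 10.0, "excessive": 14.0}


@dataclass
class CohortConfig:
    """Study-design and signal parameters of a synthetic cohort."""

    n_subjects: int = 43
    games: tuple = SessionTable.GAMES
    levels: tuple = SessionTable.ANALYSIS_LEVELS
    timepoints: tuple = SessionTable.TIMEPOINTS
    phases: tuple = (1,)
    true_icc: float = 0.85
    baseline_rr_mean: float = 850.0  # ms, on-task older-adult regime
    baseline_rr_sd: float = 80.0  # ms between subjects
    level_effect_rr: dict = field(default_factory=lambda: dict(DEFAULT_LEVEL_EFFECT))
    hf_amp_by_level: dict = field(default_factory=lambda: dict(DEFAULT_HF_AMP))
    resp_freq: float = 0.25  # Hz
    lf_amp: float = 25.0  # ms
    trend_amp: float = 20.0  # ms slow drift
    trend_freq: float = 0.005  # Hz
    noise_sd: float = 20.0  # ms white beat-to-beat noise
    artifact_rate: float = 0.0
    artifact_kinds: tuple = ("missed", "extra", "ectopic")
    trial_duration_s: float = 90.0
    tlx_mean_by_level: dict = field(default_factory=lambda: dict(DEFAULT_TLX_MEAN))
    tlx_sd: float = 3.0
    #: retest recordings replicate the test recordings exactly (identity cohort)
    identity_retest: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.true_icc <= 1.0:
            raise ConfigError("true_icc must be in [0, 1]")
        if self.true_icc == 0.0:
            raise ConfigError(
                "true_icc = 0 needs infinite occasion noise; choose > 0"
            )
        if not self.artifact_rate < 0.5:
            raise ConfigError("artifact_rate must be < 0.5")
        shifts = [self.level_effect_rr[lv] for lv in self.levels]
        if any(a < b for a, b in zip(shifts, shifts[1:])):
            raise ConfigError(
                "level_effect_rr must be monotone: RR shortens as demand rises"
            )
        floor = (
            self.baseline_rr_mean
            + min(shifts)
            - 4 * self.baseline_rr_sd
            - sum(self.hf_amp_by_level.values()) / len(self.hf_amp_by_level)
            - self.lf_amp
            - self.trend_amp
        )
        if floor <= 100:
            raise ConfigError("parameters drive intervals towards <= 0 ms")

    @property
    def occasion_sd(self) -> float:
        """Occasion noise keeping between/(between+occasion) at true_icc."""
        if self.true_icc == 1.0:
            return 0.0
        return self.baseline_rr_sd * np.sqrt((1 - self.true_icc) / self.true_icc)


@dataclass
class GroundTruth:
    """Latent quantities serialized alongside every generated cohort."""

    subject_baselines: dict  # subject_id -> ms
    latent_mrr: dict  # "subject|phase|game|level|timepoint" -> ms
    hf_amp: dict  # same key -> ms
    artifact_indices: dict  # same key -> list of perturbed beat indices
    occasion_sd: float = 0.0
    true_icc: float = np.nan

    @staticmethod
    def key(subject, phase, game, level, timepoint) -> str:
        return f"{subject}|{phase}|{game}|{level}|{timepoint}"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_rr(
    subject_baseline: float,
    level_shift: float,
    hf_amp: float,
    duration_s: float,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> RRSeries:
    """One recording: RR(t) = baseline + shift + HF & LF sinusoids + trend + noise.

    Beats accumulate sequentially so the oscillations are sampled at the
    (uneven) beat times, as in a real tachogram.  Intervals are kept
    positive by construction (floored well above 0).
    """
    mean_rr = subject_baseline + level_shift
    if mean_rr - hf_amp - cfg.lf_amp - cfg.trend_amp <= 0:
        raise ConfigError("parameters drive intervals <= 0")
    phi_lf = rng.uniform(0, 2 * np.pi)
    phi_tr = rng.uniform(0, 2 * np.pi)
    t = 0.0
    out = []
    while t < duration_s:
        rr = (
            mean_rr
            + hf_amp * np.sin(2 * np.pi * cfg.resp_freq * t)
            + cfg.lf_amp * np.sin(2 * np.pi * 0.1 * t + phi_lf)
            + cfg.trend_amp * np.sin(2 * np.pi * cfg.trend_freq * t + phi_tr)
            + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
        )
        rr = max(rr, 250.0)
        out.append(rr)
        t += rr / 1000.0
    return RRSeries(np.asarray(out))


def inject_artifacts(
    series: RRSeries,
    rate: float,
    kinds=("missed", "extra", "ectopic"),
    rng: np.random.Generator | None = None,
):
    """Perturb randomly selected beats; returns (series, truth indices).

    missed = two intervals merged into one; extra = one interval split in
    two; ectopic = the beat time shifted by 20-40% of the interval
    (shortening one interval, lengthening its neighbour).  Truth indices
    refer to the *perturbed* series.  Selections keep >= 3 beats apart so
    artifacts never overlap.
    """
    if rng is None:
        rng = np.random.default_rng()
    if rate >= 0.5:
        raise ConfigError("artifact rate must be < 0.5")
    rr = series.intervals.copy()
    n = rr.size
    n_target = int(round(rate * n))
    if n_target == 0 or n < 10:
        return RRSeries(rr, meta=dict(series.meta)), []
    candidates = rng.permutation(np.arange(2, n - 2))
    chosen = []
    for c in candidates:
        if all(abs(c - o) >= 3 for o in chosen):
            chosen.append(int(c))
        if len(chosen) == n_target:
            break
    chosen.sort(reverse=True)
    kinds = tuple(kinds)
    events = []  # (original index, kind)
    for idx in chosen:
        kind = kinds[rng.integers(len(kinds))]
        if kind == "missed":
            rr = np.concatenate([rr[:idx], [rr[idx] + rr[idx + 1]], rr[idx + 2:]])
        elif kind == "extra":
            frac = rng.uniform(0.4, 0.6)
            rr = np.concatenate(
                [rr[:idx], [rr[idx] * frac, rr[idx] * (1 - frac)], rr[idx + 1:]]
            )
        else:  # ectopic: shift the beat terminating interval idx
            delta = rng.uniform(0.2, 0.4) * rr[idx] * rng.choice([-1.0, 1.0])
            rr[idx] += delta
            rr[idx + 1] -= delta
        events.append((idx, kind))
    # map original indices to output indices (splits/merges shift later beats,
    # but events were applied back-to-front so earlier indices are stable)
    truth = []
    shift = 0
    for idx, kind in sorted(events):
        if kind == "missed":
            truth.append(idx + shift)
            shift -= 1
        elif kind == "extra":
            truth.extend([idx + shift, idx + shift + 1])
            shift += 1
        else:
            truth.extend([idx + shift, idx + shift + 1])
    return RRSeries(rr, meta=dict(series.meta)), sorted(truth)


def _tlx_row(level: str, cfg: CohortConfig, rng: np.random.Generator) -> dict:
    mu = cfg.tlx_mean_by_level[level]
    vals = np.clip(np.round(rng.normal(mu, cfg.tlx_sd, size=6)), 0, 20).astype(int)
    return dict(zip(SessionTable.TLX, vals.tolist()))


def generate_cohort(
    cfg: CohortConfig,
    out_dir=None,
    signals: bool = True,
):
    """Generate a full cohort; returns (SessionTable, GroundTruth, series map).

    With ``signals=True`` every (subject, phase, game, level, timepoint)
    gets an R-R recording of ``trial_duration_s``; the returned mapping
    takes the ground-truth key to its :class:`RRSeries`.  With
    ``signals=False`` (summary mode) the latent condition-level mean RR
    goes straight into the ``mrr_ms`` column and the series map is empty.
    When ``out_dir`` is given, RR text files, the session CSV and the
    ground-truth JSON are written there.
    """
    rng = np.random.default_rng(cfg.seed)
    subjects = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    baselines = {
        s: float(cfg.baseline_rr_mean + rng.normal(0.0, cfg.baseline_rr_sd))
        for s in subjects
    }
    occ_sd = cfg.occasion_sd
    truth = GroundTruth(
        subject_baselines=baselines,
        latent_mrr={},
        hf_amp={},
        artifact_indices={},
        occasion_sd=occ_sd,
        true_icc=cfg.true_icc,
    )
    rows = []
    series_map: dict[str, RRSeries] = {}
    for s in subjects:
        for phase in cfg.phases:
            for game in cfg.games:
                for level in cfg.levels:
                    tlx_by_tp = {
                        tp: _tlx_row(level, cfg, rng) for tp in cfg.timepoints
                    }
                    first_tp = cfg.timepoints[0]
                    for tp in cfg.timepoints:
                        if cfg.identity_retest and tp != first_tp:
                            ref = GroundTruth.key(s, phase, game, level, first_tp)
                            latent = truth.latent_mrr[ref]
                        else:
                            occ = rng.normal(0.0, occ_sd) if occ_sd > 0 else 0.0
                            latent = baselines[s] + cfg.level_effect_rr[level] + occ
                        key = GroundTruth.key(s, phase, game, level, tp)
                        truth.latent_mrr[key] = float(latent)
                        truth.hf_amp[key] = float(cfg.hf_amp_by_level[level])
                        row = {
                            "subject_id": s,
                            "phase": phase,
                            "game": game,
                            "level": level,
                            "timepoint": tp,
                            **tlx_by_tp[tp],
                            "quality_pass": True,
                        }
                        if signals:
                            if cfg.identity_retest and tp != first_tp:
                                ref = GroundTruth.key(s, phase, game, level, first_tp)
                                ser = RRSeries(
                                    series_map[ref].intervals.copy(),
                                    meta=dict(series_map[ref].meta),
                                )
                            else:
                                ser = generate_rr(
                                    latent,
                                    0.0,
                                    cfg.hf_amp_by_level[level],
                                    cfg.trial_duration_s,
                                    cfg,
                                    rng,
                                )
                                if cfg.artifact_rate > 0:
                                    ser, idx = inject_artifacts(
                                        ser, cfg.artifact_rate, cfg.artifact_kinds, rng
                                    )
                                    truth.artifact_indices[key] = idx
                            series_map[key] = ser
                        else:
                            row["mrr_ms"] = latent
                        rows.append(row)
    table = SessionTable(pd.DataFrame(rows))
    if out_dir is not None:
        out = Path(out_dir)
        (out / "rr").mkdir(parents=True, exist_ok=True)
        for key, ser in series_map.items():
            fname = key.replace("|", "_") + ".txt"
            write_rr_text(ser, out / "rr" / fname)
        table.to_csv(out / "sessions.csv")
        truth.to_json(out / "ground_truth.json")
    return table, truth, series_map
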