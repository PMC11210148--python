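"""R-R interval series containers, file I/O, and analysis-window selection.

The atomic signal object is :class:`RRSeries`: an ordered sequence of
inter-beat intervals in milliseconds together with the cumulative beat
times.  Files follow the plain-text dialect common to wearable exports:
one value per line, ``#`` comments, milliseconds by default.  A
CSV-with-timestamp reader accepts ``time_s,rr_ms`` columns.

Window selection follows tachogram convention: an R-R interval is defined
by its terminating R peak, so a beat belongs to a window if its *ending*
time falls in the half-open interval ``(t0, t1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RRParseError, ValidationError

__all__ = [
    "RRSeries",
    "Tachogram",
    "SessionTable",
    "read_rr_text",
    "read_rr_csv",
    "write_rr_text",
    "segment_last",
    "segment_window",
]


@dataclass
class RRSeries:
    """An ordered inter-beat-interval sequence in milliseconds.

    Parameters
    ----------
    intervals : array-like of float
        Strictly positive R-R intervals in ms.
    meta : dict, optional
        Free-form labels (subject, condition, timepoint, source path ...).
    """

    intervals: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1:
            raise ValidationError("intervals must be a 1-D sequence")
        if iv.size and not np.all(iv > 0):
            bad = int(np.flatnonzero(iv <= 0)[0])
            raise ValidationError(
                f"non-positive R-R interval at beat {bad}: {iv[bad]!r} ms"
            )
        self.intervals = iv

    @property
    def t_beat(self) -> np.ndarray:
        """Cumulative beat times in seconds (time of each terminating R peak)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.intervals)) / 1000.0

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass
class Tachogram:
    """R-R derived values on beat times that need not be positive.

    Used for detrended tachograms, where values are zero-centred
    deviations in ms and cannot satisfy the :class:`RRSeries` positivity
    invariant.
    """

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValidationError("t and values must have equal length")

    def __len__(self) -> int:
        return int(self.t.size)


def read_rr_text(path, unit: str = "ms") -> RRSeries:
    """Read a plain-text R-R file: one numeric token per non-comment line.

    ``unit`` is ``"ms"`` or ``"s"``; the returned series is always in ms.
    """
    if unit not in ("ms", "s"):
        raise ValueError(f"unit must be 'ms' or 's', got {unit!r}")
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise RRParseError(
                    f"{path.name}:{lineno}: non-numeric token {line!r}"
                ) from None
            values.append(v)
    iv = np.asarray(values, dtype=float)
    if unit == "s":
        iv = iv * 1000.0
    return RRSeries(iv, meta={"path": str(path), "unit": "ms"})


def read_rr_csv(path) -> RRSeries:
    """Read a timestamped CSV export with columns ``time_s, rr_ms``."""
    df = pd.read_csv(path)
    missing = {"time_s", "rr_ms"} - set(df.columns)
    if missing:
        raise RRParseError(f"{path}: missing columns {sorted(missing)}")
    return RRSeries(df["rr_ms"].to_numpy(dtype=float), meta={"path": str(path)})


def _format_ms(v: float) -> str:
    # integers render without a decimal point so integer-ms data round-trips
    # bit-exactly; non-integers keep full precision
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_rr_text(series: RRSeries, path) -> None:
    """Write ``series`` in the plain-text dialect read by :func:`read_rr_text`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# rr intervals [ms], one per line\n")
        for v in series.intervals:
            fh.write(_format_ms(v) + "\n")


def segment_last(series: RRSeries, duration_s: float = 60.0) -> RRSeries:
    """Select the trailing analysis window, e.g. the last 60 s of a trial.

    Returns the shortest suffix of beats spanning at least ``duration_s``
    (so the window is fully covered; the overshoot is less than one
    interval).  Raises :class:`InsufficientDataError` when the recording
    is shorter than the window.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    total = series.duration_s
    if total < duration_s:
        raise InsufficientDataError(
            f"recording spans {total:.3f} s < requested {duration_s} s window",
            available=total,
        )
    # walk back from the end until the suffix covers the window
    csum = np.cumsum(series.intervals[::-1]) / 1000.0
    m = int(np.searchsorted(csum, duration_s - 1e-12) + 1)
    m = min(m, len(series))
    return RRSeries(series.intervals[-m:].copy(), meta=dict(series.meta))


def segment_window(series: RRSeries, t0: float, t1: float) -> RRSeries:
    """Beats whose terminating R peak falls in ``(t0, t1]`` seconds."""
    if not t0 < t1:
        raise ValueError(f"inverted window bounds: t0={t0} >= t1={t1}")
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    if t1 > series.duration_s + 1e-9:
        raise ValueError(
            f"t1={t1} s exceeds recording duration {series.duration_s:.3f} s"
        )
    t = series.t_beat
    mask = (t > t0 + 1e-12) & (t <= t1 + 1e-12)
    return RRSeries(series.intervals[mask].copy(), meta=dict(series.meta))


# ---------------------------------------------------------------------------
# Session table


class SessionTable:
    """Long-format study table: one row per (subject, phase, game, level, timepoint).

    Carries per-recording vm-HRV metrics, raw NASA-TLX subscores and the
    data-quality flag.  Missing recordings stay as missing values and are
    excluded downstream, never imputed.
    """

    KEY = ["subject_id", "phase", "game", "level", "timepoint"]
    METRICS = [
        "mrr_ms",
        "mean_hr_bpm",
        "rmssd_ms",
        "hf_ms2",
        "hf_nu",
        "sd1_ms",
        "pns_index",
    ]
    TLX = [
        "tlx_effort",
        "tlx_mental",
        "tlx_temporal",
        "tlx_physical",
        "tlx_performance",
        "tlx_frustration",
    ]
    COLUMNS = KEY + METRICS + TLX + ["quality_pass"]

    GAMES = ("Simple", "Targets", "Tetris", "Simon", "Habitats")
    #: only the standardized demand levels enter reliability/validity analysis
    ANALYSIS_LEVELS = ("easy", "challenging", "excessive")
    LEVELS = ("adaptive",) + ANALYSIS_LEVELS
    TIMEPOINTS = ("test", "retest")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        extra = [c for c in df.columns if c not in self.COLUMNS]
        df = df[self.COLUMNS + extra]
        if df.duplicated(subset=self.KEY).any():
            dup = df[df.duplicated(subset=self.KEY)].iloc[0]
            raise ValidationError(
                "duplicate session key: "
                + ", ".join(str(dup[k]) for k in self.KEY)
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path) -> "SessionTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def analysis_rows(self) -> pd.DataFrame:
        """Rows at the standardized demand levels (adaptive warm-ups excluded)."""
        return self.df[self.df["level"].isin(self.ANALYSIS_LEVELS)]

    def complete_pairs(self, metric: str, phase, game, level) -> pd.DataFrame:
        """Subjects x (test, retest) values for one condition, complete cases only.

        Rows failing the quality gate or with a missing metric are dropped
        pairwise, matching per-condition sample sizes that vary by game.
        """
        sub = self.df[
            (self.df["phase"] == phase)
            & (self.df["game"] == game)
            & (self.df["level"] == level)
        ]
        ok = sub[sub["quality_pass"].fillna(False).astype(bool)]
        wide = ok.pivot_table(
            index="subject_id", columns="timepoint", values=metric, aggfunc="first"
        )
        for tp in self.TIMEPOINTS:
            if tp not in wide.columns:
                wide[tp] = np.nan
        wide = wide[list(self.TIMEPOINTS)].dropna()
        return wide
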