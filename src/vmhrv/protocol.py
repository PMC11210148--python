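"""Exercise-intensity prescription, HR stability checks, NASA-TLX and reactivity.

The physical-intensity arm of the protocol: a Karvonen target at 40% of
heart rate reserve with age-predicted HRmax (208 - 0.7*age), a stepping
ramp test (start 80 steps/min, +5 every 20 s, 20-s averaged HR), a
+/- 5 bpm resting-HR stability rule between trials, the raw NASA task
load index (unweighted sum of six 0-20 subscales), and rest-to-task
reactivity deltas of the vm-HRV metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import TargetNotReachedError, ValidationError
from .hrv_metrics import HRVMetrics

__all__ = [
    "ProtocolParams",
    "RampConfig",
    "TlxRating",
    "age_predicted_hrmax",
    "karvonen_target",
    "ramp_test",
    "hr_rest_stable",
    "rtlx",
    "reactivity",
]


@dataclass
class ProtocolParams:
    age: float  # years
    hr_rest: float  # bpm
    hr_max: float | None = None  # measured; age-predicted when None
    target_fraction: float = 0.40  # fraction of heart rate reserve
    moderate_band: tuple = (0.40, 0.59)

    def __post_init__(self):
        if self.hr_max is None:
            self.hr_max = age_predicted_hrmax(self.age)
        if not 0 < self.hr_rest < self.hr_max:
            raise ValueError(
                f"need 0 < hr_rest ({self.hr_rest}) < hr_max ({self.hr_max})"
            )
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must be in (0, 1)")


@dataclass
class RampConfig:
    start_spm: float = 80.0  # steps/min
    increment_spm: float = 5.0
    stage_s: float = 20.0

    def __post_init__(self):
        if min(self.start_spm, self.increment_spm, self.stage_s) <= 0:
            raise ValueError("ramp parameters must be positive")


@dataclass
class TlxRating:
    """Raw NASA-TLX subscores, each an integer 0-20."""

    effort: int
    mental: int
    temporal: int
    physical: int
    performance: int
    frustration: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 20):
                raise ValidationError(
                    f"TLX subscore {f.name}={v!r} must be an integer in [0, 20]"
                )


def age_predicted_hrmax(age: float) -> float:
    """Age-predicted maximal heart rate: 208 - 0.7 * age (bpm)."""
    if not 0 < age < 120:
        raise ValueError(f"age {age} outside (0, 120) years")
    return 208.0 - 0.7 * age


def karvonen_target(p: ProtocolParams) -> float:
    """Karvonen target HR: (HRmax - HRrest) * fraction + HRrest (bpm)."""
    return (p.hr_max - p.hr_rest) * p.target_fraction + p.hr_rest


def ramp_test(hr_stream, cfg: RampConfig, hr_target: float) -> float:
    """Stepping frequency (steps/min) of the first stage whose 20-s mean HR
    reaches ``hr_target``.

    ``hr_stream`` is a sequence of (time_s, bpm) samples covering at least
    one full stage.  Raises :class:`TargetNotReachedError` (carrying the
    last simulated stage) when the stream ends first.
    """
    stream = np.asarray(hr_stream, dtype=float)
    if stream.ndim != 2 or stream.shape[1] != 2:
        raise ValueError("hr_stream must be (time_s, bpm) pairs")
    t, hr = stream[:, 0], stream[:, 1]
    if t.max() - t.min() < cfg.stage_s:
        raise TargetNotReachedError(
            "stream shorter than one ramp stage", last_stage_spm=None
        )
    stage = 0
    last_spm = None
    while True:
        lo = t.min() + stage * cfg.stage_s
        hi = lo + cfg.stage_s
        mask = (t >= lo) & (t < hi)
        if not mask.any() or hi > t.max() + 1e-9:
            raise TargetNotReachedError(
                f"HR target {hr_target:.1f} bpm not reached; "
                f"last complete stage {last_spm} steps/min",
                last_stage_spm=last_spm,
            )
        spm = cfg.start_spm + stage * cfg.increment_spm
        last_spm = spm
        if hr[mask].mean() >= hr_target:
            return spm
        stage += 1


def hr_rest_stable(current_rest: float, baseline_rest: float, tol: float = 5.0) -> bool:
    """Within +/- ``tol`` bpm of the baseline resting HR (inclusive band)."""
    if current_rest <= 0 or baseline_rest <= 0:
        raise ValueError("heart rates must be positive")
    return abs(current_rest - baseline_rest) <= tol


def rtlx(r: TlxRating) -> int:
    """Raw NASA-TLX: unweighted sum of the six subscales (0-120)."""
    return int(
        r.effort + r.mental + r.temporal + r.physical + r.performance + r.frustration
    )


def reactivity(on_task: HRVMetrics, rest: HRVMetrics) -> dict:
    """Absolute change from resting state to on-task, per metric.

    Missing (NaN) components propagate to a missing delta.
    """
    task_d, rest_d = on_task.as_dict(), rest.as_dict()
    return {k: task_d[k] - rest_d[k] for k in task_d}
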