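"""The vagally-mediated HRV parameter set for one analyzed segment.

Computes mRR, mean HR, RMSSD, absolute HF power (0.15-0.4 Hz), HF in
normal units HF/(total - VLF), Poincare SD1, and the composite
parasympathetic tone score (PNS-Index).  Conventions:

* mRR comes from the *undetrended* corrected series (detrending
  zero-centres the tachogram and would destroy it); variability metrics
  (RMSSD, SD1, spectra) are computed on the detrended tachogram.
* RMSSD uses the n-1 successive differences of n beats; SD1 is defined
  through the algebraic identity SD1 = RMSSD / sqrt(2) (successive
  differences taken about zero), so the identity holds exactly.
* Spectra: cubic-spline resampling at 4 Hz, Welch with a Hann window and
  50% overlap, segment length min(150 s, record duration) - a single
  tapered periodogram for 60-s windows.  The per-segment mean is removed,
  so band powers measure oscillatory power only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, UndefinedMetricError
from .preprocess import (
    CorrectionReport,
    DetrendConfig,
    correct_beats,
    detect_artifacts,
    detrend_smoothness_priors,
    quality_gate,
)
from .rr_ingest import RRSeries, Tachogram

__all__ = [
    "SpectralBands",
    "SpectralEstimate",
    "HRVMetrics",
    "PnsNormals",
    "mean_rr",
    "rmssd",
    "poincare_sd1",
    "psd_welch",
    "hf_nu",
    "pns_index",
    "compute_all",
]


@dataclass(frozen=True)
class SpectralBands:
    """Standard short-term HRV bands in Hz (contiguous, ordered)."""

    vlf: tuple = (0.00, 0.04)
    lf: tuple = (0.04, 0.15)
    hf: tuple = (0.15, 0.40)

    def __post_init__(self):
        edges = [*self.vlf, *self.lf, *self.hf]
        if not (
            self.vlf[0] < self.vlf[1] == self.lf[0] < self.lf[1] == self.hf[0] < self.hf[1]
        ):
            raise ValueError(f"bands must be contiguous and ordered, got {edges}")


@dataclass
class SpectralEstimate:
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # ms^2/Hz
    total_power: float  # ms^2
    band_powers: dict  # {"vlf","lf","hf"} -> ms^2


@dataclass
class HRVMetrics:
    """One recording's vm-HRV parameter set (missing values are NaN)."""

    mrr: float = np.nan  # ms
    mean_hr: float = np.nan  # bpm
    rmssd: float = np.nan  # ms
    hf: float = np.nan  # ms^2
    hf_nu: float = np.nan  # in [0, 1]
    sd1: float = np.nan  # ms
    pns_index: float = np.nan

    def as_dict(self) -> dict:
        return {
            "mrr_ms": self.mrr,
            "mean_hr_bpm": self.mean_hr,
            "rmssd_ms": self.rmssd,
            "hf_ms2": self.hf,
            "hf_nu": self.hf_nu,
            "sd1_ms": self.sd1,
            "pns_index": self.pns_index,
        }


@dataclass
class PnsNormals:
    """Normative resting values used to standardize the PNS-Index components.

    Defaults follow published resting normative ranges for short-term
    recordings (mRR ~926 +/- 90 ms, RMSSD ~42 +/- 15 ms) with SD1 in
    normalized units SD1/(SD1+SD2) around 0.32 +/- 0.08; all are
    configuration, not measurement.
    """

    mrr_mean: float = 926.0
    mrr_sd: float = 90.0
    rmssd_mean: float = 42.0
    rmssd_sd: float = 15.0
    sd1nu_mean: float = 0.32
    sd1nu_sd: float = 0.08

    def __post_init__(self):
        if min(self.mrr_sd, self.rmssd_sd, self.sd1nu_sd) <= 0:
            raise ValueError("normative SDs must be positive")


def _values(x) -> np.ndarray:
    if isinstance(x, RRSeries):
        return x.intervals
    if isinstance(x, Tachogram):
        return x.values
    return np.asarray(x, dtype=float)


def mean_rr(series) -> float:
    """Arithmetic mean R-R interval in ms."""
    v = _values(series)
    if v.size < 1:
        raise InsufficientDataError("mean RR needs >= 1 beat", available=0)
    return float(v.mean())


def mean_hr(series) -> float:
    return 60000.0 / mean_rr(series)


def rmssd(series) -> float:
    """Root mean square of successive differences, ms."""
    v = _values(series)
    if v.size < 2:
        raise InsufficientDataError("RMSSD needs >= 2 beats", available=v.size)
    d = np.diff(v)
    return float(np.sqrt(np.mean(d**2)))


def poincare_sd1(series) -> float:
    """Poincare dispersion perpendicular to the identity line; RMSSD/sqrt(2)."""
    return rmssd(series) / np.sqrt(2.0)


def poincare_sd2(series) -> float:
    """Dispersion along the identity line via sqrt(2 SDNN^2 - SD1^2)."""
    v = _values(series)
    if v.size < 2:
        raise InsufficientDataError("SD2 needs >= 2 beats", available=v.size)
    sdnn = float(np.std(v, ddof=0))
    sd1 = poincare_sd1(series)
    return float(np.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0)))


def psd_welch(
    series,
    resample_hz: float = 4.0,
    window_s: float | None = None,
    overlap: float = 0.5,
    bands: SpectralBands | None = None,
) -> SpectralEstimate:
    """Welch power spectral density of the (detrended) tachogram.

    Accepts a :class:`Tachogram` (uneven beat times; cubic-spline
    resampled), an :class:`RRSeries`, or an already-even array.  Band
    powers integrate the PSD with the rectangle rule on the grid.
    """
    bands = bands or SpectralBands()
    if isinstance(series, (RRSeries, Tachogram)):
        t = series.t_beat if isinstance(series, RRSeries) else series.t
        z = _values(series)
        if t.size < 4:
            raise InsufficientDataError("spectrum needs >= 4 beats", available=t.size)
        duration = float(t[-1] - t[0])
        grid = np.arange(t[0], t[-1] + 1e-9, 1.0 / resample_hz)
        x = CubicSpline(t, z)(grid)
    else:
        x = np.asarray(series, dtype=float)
        duration = (x.size - 1) / resample_hz
    if window_s is None:
        window_s = min(150.0, duration)
    if duration + 1e-9 < window_s:
        raise InsufficientDataError(
            f"segment {duration:.1f} s shorter than Welch window {window_s} s",
            available=duration,
        )
    nperseg = max(8, int(round(window_s * resample_hz)))
    nperseg = min(nperseg, x.size)
    freqs, psd = sps.welch(
        x,
        fs=resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap * nperseg),
        detrend="constant",
    )
    df = freqs[1] - freqs[0] if freqs.size > 1 else 0.0
    total = float(np.sum(psd) * df)
    powers = {}
    for name in ("vlf", "lf", "hf"):
        lo, hi = getattr(bands, name)
        mask = (freqs > lo) & (freqs <= hi)
        powers[name] = float(np.sum(psd[mask]) * df)
    return SpectralEstimate(freqs=freqs, psd=psd, total_power=total, band_powers=powers)


def hf_nu(spec: SpectralEstimate) -> float:
    """HF power in normal units: HF / (total power - VLF)."""
    denom = spec.total_power - spec.band_powers["vlf"]
    if denom <= 0:
        raise UndefinedMetricError(
            f"total power {spec.total_power:g} does not exceed VLF "
            f"{spec.band_powers['vlf']:g}; HFnu undefined"
        )
    return float(spec.band_powers["hf"] / denom)


def pns_index(
    mrr: float,
    rmssd_val: float,
    sd1: float,
    sd2: float,
    normals: PnsNormals | None = None,
) -> float:
    """Composite parasympathetic tone: mean z of mRR, RMSSD and SD1 (n.u.).

    SD1 enters in normalized units SD1/(SD1+SD2); each component is
    standardized against the configured resting normative values.
    """
    normals = normals or PnsNormals()
    if sd1 + sd2 == 0:
        raise UndefinedMetricError("SD1 + SD2 = 0; normalized SD1 undefined")
    sd1_nu = sd1 / (sd1 + sd2)
    z = (
        (mrr - normals.mrr_mean) / normals.mrr_sd,
        (rmssd_val - normals.rmssd_mean) / normals.rmssd_sd,
        (sd1_nu - normals.sd1nu_mean) / normals.sd1nu_sd,
    )
    return float(np.mean(z))


def compute_all(
    series: RRSeries,
    cfg: DetrendConfig | None = None,
    bands: SpectralBands | None = None,
    normals: PnsNormals | None = None,
    report: CorrectionReport | None = None,
    *,
    welch_window_s: float | None = None,
) -> HRVMetrics:
    """Full metric set for one quality-passed segment.

    Orchestrates correct -> (mRR on the corrected series) -> detrend ->
    (RMSSD, SD1, spectra, HFnu, PNS-Index on the detrended tachogram).
    ``report`` may carry labels from an upstream detection pass; otherwise
    detection runs here.  Degenerate metrics come back as NaN, never 0.
    """
    cfg = cfg or DetrendConfig()
    bands = bands or SpectralBands()
    normals = normals or PnsNormals()
    if report is None:
        report = detect_artifacts(series)
    if not quality_gate(report):
        raise UndefinedMetricError(
            f"segment failed quality gate ({report.fraction_corrected:.1%} corrected)"
        )
    corrected = report.corrected
    if corrected is None:
        corrected = correct_beats(series, report)
    m = HRVMetrics()
    m.mrr = mean_rr(corrected)
    m.mean_hr = 60000.0 / m.mrr
    detr = detrend_smoothness_priors(corrected, cfg)
    m.rmssd = rmssd(detr)
    m.sd1 = poincare_sd1(detr)
    sd2 = poincare_sd2(detr)
    try:
        spec = psd_welch(
            detr, resample_hz=cfg.resample_hz, window_s=welch_window_s, bands=bands
        )
        m.hf = spec.band_powers["hf"]
        m.hf_nu = hf_nu(spec)
    except (InsufficientDataError, UndefinedMetricError):
        pass  # stays NaN
    try:
        m.pns_index = pns_index(m.mrr, m.rmssd, m.sd1, sd2, normals)
    except UndefinedMetricError:
        pass
    return m
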