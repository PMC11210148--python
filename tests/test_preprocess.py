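"""Artifact detection/correction, the quality gate, and detrending."""

import numpy as np
import pytest

from vmhrv import (
    CorrectionReport,
    DetrendConfig,
    InsufficientDataError,
    RRSeries,
    UncorrectableSignalError,
    correct_beats,
    detect_artifacts,
    detect_artifacts_median,
    detrend_smoothness_priors,
    quality_gate,
)


def series_with_missed(n=100, at=50):
    rr = np.full(n, 1000.0)
    rr[at] = 2000.0  # two beats merged by a missed detection
    return RRSeries(rr)


def series_with_extra(n=100, at=50):
    rr = np.full(n, 1000.0)
    return RRSeries(np.concatenate([rr[:at], [500.0, 500.0], rr[at + 1:]]))


class TestDetect:
    def test_uniform_all_normal(self, uniform_series):
        rep = detect_artifacts(uniform_series)
        assert rep.n_corrected == 0
        assert rep.fraction_corrected == 0.0

    def test_single_long_interval_is_missed(self):
        rep = detect_artifacts(series_with_missed())
        # oracle: exhaustive scan for intervals > 1.5x the local median
        s = series_with_missed()
        med = np.median(s.intervals)
        oracle = np.flatnonzero(s.intervals > 1.5 * med)
        flagged = np.flatnonzero(rep.labels == "missed")
        assert np.array_equal(flagged, oracle)
        assert rep.fraction_corrected == pytest.approx(1 / 100)

    def test_split_beat_pair_is_extra(self):
        s = series_with_extra()
        rep = detect_artifacts(s)
        oracle = np.flatnonzero(s.intervals < 0.5 * np.median(s.intervals) + 1e-9)
        flagged = np.flatnonzero(rep.labels == "extra")
        assert np.array_equal(flagged, oracle)
        assert rep.n_corrected == 2

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_artifacts(RRSeries(np.full(5, 1000.0)))

    def test_fallback_detector_agrees_on_constructed_series(self):
        for s in (series_with_missed(), series_with_extra()):
            a = detect_artifacts(s)
            b = detect_artifacts_median(s)
            assert np.array_equal(a.labels != "normal", b.labels != "normal")

    def test_noisy_clean_series_mostly_normal(self, rng):
        s = RRSeries(1000 + rng.normal(0, 25, size=300))
        rep = detect_artifacts(s)
        assert rep.fraction_corrected < 0.02


class TestCorrect:
    def test_identity_on_all_normal(self, uniform_series):
        rep = detect_artifacts(uniform_series)
        out = correct_beats(uniform_series, rep)
        assert np.array_equal(out.intervals, uniform_series.intervals)

    def test_missed_split_matches_even_split_oracle(self):
        s = RRSeries(np.array([1000.0] * 10 + [2000.0] + [1000.0] * 10))
        rep = detect_artifacts(s)
        out = correct_beats(s, rep)
        assert len(out) == len(s) + 1
        # on a flat series the spline-shaped split must stay within
        # +/- 50 ms of the even split
        assert np.all(np.abs(out.intervals - 1000.0) < 50.0)
        assert out.duration_s == pytest.approx(s.duration_s)

    def test_extra_merge_preserves_duration(self):
        s = series_with_extra()
        rep = detect_artifacts(s)
        out = correct_beats(s, rep)
        assert len(out) == 100
        assert out.duration_s == pytest.approx(s.duration_s)

    def test_duration_preserved_within_2pct(self, rng):
        from vmhrv import inject_artifacts

        base = RRSeries(900 + rng.normal(0, 20, size=400))
        perturbed, _ = inject_artifacts(base, 0.04, rng=rng)
        rep = detect_artifacts(perturbed)
        out = correct_beats(perturbed, rep)
        assert abs(out.duration_s - perturbed.duration_s) < 0.02 * perturbed.duration_s

    def test_majority_flagged_refused(self, uniform_series):
        labels = np.full(100, "ectopic", dtype=object)
        rep = CorrectionReport(labels, None, 100, 100)
        with pytest.raises(UncorrectableSignalError):
            correct_beats(uniform_series, rep)

    def test_no_oscillating_corrections(self, rng):
        from vmhrv import inject_artifacts

        base = RRSeries(900 + rng.normal(0, 15, size=300))
        perturbed, _ = inject_artifacts(base, 0.03, rng=rng)
        rep1 = detect_artifacts(perturbed)
        out = correct_beats(perturbed, rep1)
        rep2 = detect_artifacts(out)
        assert rep2.n_corrected <= rep1.n_corrected


class TestGate:
    @pytest.mark.parametrize(
        "n_corr,n_tot,expected",
        [(4, 100, True), (5, 100, False), (0, 100, True)],
    )
    def test_strict_5pct_boundary(self, n_corr, n_tot, expected):
        labels = np.array(
            ["ectopic"] * n_corr + ["normal"] * (n_tot - n_corr), dtype=object
        )
        rep = CorrectionReport(labels, None, n_tot, n_corr)
        assert quality_gate(rep) is expected


class TestDetrend:
    def test_constant_series_annihilated(self):
        out = detrend_smoothness_priors(RRSeries(np.full(200, 950.0)))
        assert np.max(np.abs(out.values)) < 1e-6

    def test_lambda_zero_annihilates_everything(self, rng):
        s = RRSeries(900 + 50 * rng.standard_normal(200).cumsum() * 0.01)
        out = detrend_smoothness_priors(s, DetrendConfig(lam=0))
        assert np.max(np.abs(out.values)) < 1e-9

    def test_linear_ramp_removed(self):
        # oracle: a dense direct solve of the penalized system on a ramp;
        # the trend of a pure ramp is the ramp itself away from edges
        n = 64
        rr = np.linspace(800, 1200, n)
        out = detrend_smoothness_priors(RRSeries(rr))
        core = out.values[8:-8]
        assert np.max(np.abs(core)) < 0.01 * (1200 - 800)

    def test_dense_solve_oracle_equivalence(self):
        # independent dense linear-algebra route for the same trend system
        rng = np.random.default_rng(3)
        rr = 900 + 30 * np.sin(0.05 * np.arange(128)) + rng.normal(0, 5, 128)
        s = RRSeries(rr)
        cfg = DetrendConfig()
        t = s.t_beat
        from scipy.interpolate import CubicSpline

        grid = np.arange(t[0], t[-1] + 1e-9, 1.0 / cfg.resample_hz)
        zg = CubicSpline(t, rr)(grid)
        m = grid.size
        d2 = np.zeros((m - 2, m))
        for i in range(m - 2):
            d2[i, i: i + 3] = (1.0, -2.0, 1.0)
        trend = np.linalg.solve(np.eye(m) + cfg.lam**2 * d2.T @ d2, zg)
        expected = np.interp(t, grid, zg - trend)
        out = detrend_smoothness_priors(s, cfg)
        assert np.allclose(out.values, expected, atol=1e-8)

    def test_linearity(self, rng):
        a, b = 2.0, -0.5
        x = 900 + rng.normal(0, 20, 150)
        y = 950 + 30 * np.sin(0.1 * np.arange(150))
        sx, sy = RRSeries(x), RRSeries(y)
        # same beat grid: build combined series on x's beat times
        from vmhrv.rr_ingest import Tachogram

        t = sx.t_beat
        combo = Tachogram(t, a * x + b * y)
        dx = detrend_smoothness_priors(Tachogram(t, x))
        dy = detrend_smoothness_priors(Tachogram(t, y))
        dc = detrend_smoothness_priors(combo)
        assert np.allclose(dc.values, a * dx.values + b * dy.values, atol=1e-7)

    @pytest.mark.parametrize(
        "freq,retain_lo,retain_hi",
        [(0.01, 0.0, 0.10), (0.25, 0.90, 1.05)],
    )
    def test_frequency_response_at_defaults(self, freq, retain_lo, retain_hi):
        # lambda=500 on a 4 Hz grid passes the respiratory band and kills
        # sub-0.035 Hz drifts
        t = np.cumsum(np.full(600, 1000.0)) / 1000.0
        x = 1000 + 50 * np.sin(2 * np.pi * freq * t)
        out = detrend_smoothness_priors(RRSeries(x))
        core = slice(40, -40)
        retention = np.std(out.values[core]) / np.std(
            50 * np.sin(2 * np.pi * freq * t[core])
        )
        assert retain_lo <= retention <= retain_hi

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            DetrendConfig(lam=-1)

    def test_too_few_beats(self):
        with pytest.raises(InsufficientDataError):
            detrend_smoothness_priors(RRSeries([1000.0, 1000.0]))
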