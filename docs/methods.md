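# Methods

## Problem setting

A wearable chest-belt sensor exports R-R inter-beat intervals at 1 ms
resolution. During exergame trials, each participant plays several games at
three standardized levels of external task demand ("easy", "challenging",
"excessive"), twice (test and retest), for 90 s per trial; rest recordings
span 5 min. The package decides, per vm-HRV parameter and condition, whether
the measurement is reliable across occasions and whether it responds to the
demand manipulation — the two prerequisites for using it as an
internal-training-load marker.

## Signal chain

**Windowing.** An R-R interval is attributed to its terminating R peak, so a
beat belongs to a window when its ending time falls in `(t0, t1]`. On-task
analysis uses the *last* 60 s of a trial: `segment_last` returns the shortest
suffix covering the window, accepting an overshoot of less than one interval
rather than analyzing less data than prescribed. Rest analysis uses the whole
recording after the acclimatization window is cut.

**Artifact handling.** The detector follows the successive-difference /
time-varying quartile-deviation family used by clinical HRV software: beat
`i` is a candidate when `|dRR_i|` exceeds
`max(threshold_scale · QD_i, floor_ms)`, with `QD_i` the quartile deviation
of the difference series over a 91-beat window and `threshold_scale = 5.2`.
The floor (50 ms) exists because a nearly constant clean recording has
`QD ≈ 0` and would otherwise flag numerical noise. Candidates are typed by
their ratio to an 11-beat rolling median: > 1.45 → missed beat (two true
intervals merged), < 0.55 → extra detection, otherwise ectopic when an
adjacent beat deviates in the opposite direction, else misaligned; candidates
whose own interval is unremarkable (the large difference came from a
neighbour) revert to normal. A simple percent-of-local-median fallback
detector is exposed for testing. Correction redistributes time rather than
deleting it: missed intervals are split into the implied number of beats
shaped by the cubic-spline profile of the surrounding normal beats (an even
split on flat signal); runs of extra beats are merged; ectopic/misaligned
runs are replaced by the interpolated profile rescaled to the run's original
total duration. Total duration is therefore preserved exactly up to floating
error. The quality gate is strict: a segment enters analysis only when
*fewer than* 5% of its beats were corrected; 5/100 fails. The gate is applied
to the analyzed segment, not the whole recording, because that is the data
the metrics see.

**Detrending.** Slow non-stationarities are removed with the
smoothness-priors (regularized least squares) method: the tachogram is
cubic-spline resampled onto an even grid at 4 Hz (comfortably above twice the
0.4 Hz HF bound), the trend solves `(I + λ²D₂ᵀD₂)·trend = z` with `D₂` the
second-difference operator and natural boundaries (no padding), and the
grid-domain residual is linearly interpolated back to the beat times. With
the default λ = 500 at 4 Hz the empirical frequency response attenuates a
0.01 Hz drift by ≥ 98% while passing a 0.25 Hz respiratory oscillation at
≥ 99% — an equivalent cutoff of about 0.035 Hz, which we report from the
measured response rather than a formula since it depends on the grid rate.
λ = 0 reproduces the signal exactly (all-zero residual), as does any constant
input. mRR is deliberately computed from the *undetrended* corrected series:
detrending zero-centres the tachogram and would destroy the mean, while the
variability metrics (RMSSD, SD1, spectra) use the detrended values, matching
standard HRV-software convention.

## Metrics

- `mRR` — arithmetic mean interval; `mean HR = 60000/mRR`.
- `RMSSD` — root mean square of the n−1 successive differences.
- `SD1` — defined through the identity `SD1 = RMSSD/√2` (successive
  differences taken about zero rather than about their mean). The centred and
  uncentred forms differ by `(mean dRR)²`, which is negligible after
  detrending; the uncentred convention makes the identity exact, and the test
  suite asserts it globally.
- Spectra — Welch on the 4 Hz resampled tachogram, Hann window, 50% overlap,
  segment length `min(150 s, record duration)`; for 60-s windows this
  degrades to a single tapered periodogram with Δf ≈ 0.017 Hz, coarse but
  adequate for band *integrals*. The per-segment mean is removed so band
  powers measure oscillatory power only. Bands: VLF 0–0.04, LF 0.04–0.15,
  HF 0.15–0.40 Hz; powers integrate the PSD by the rectangle rule.
- `HFnu = HF/(total − VLF)`; undefined (missing, never zero) when the
  denominator is non-positive.
- `PNS-Index` — mean of three z-scores: mRR, RMSSD, and SD1 in normalized
  units `SD1/(SD1+SD2)`, each standardized against configurable resting
  normative values. Defaults (mRR 926 ± 90 ms, RMSSD 42 ± 15 ms,
  SD1nu 0.32 ± 0.08) follow published short-term resting normative ranges;
  the index's *structure* is what the downstream analysis needs — its
  absolute calibration is configuration. SD2 comes from the Poincaré identity
  `SD2 = √(2·SDNN² − SD1²)` on the same segment, keeping the operation
  self-contained.

Failed segments yield missing metrics, never zeros — zeros would corrupt the
downstream ICCs.

## Reliability statistics

**Systematic error.** A balanced two-way within-subject ANOVA
(2 timepoints × 3 levels) per game, computed from the classical
sums-of-squares decomposition on an `(n, 2, 3)` cube (each effect tested
against its subject-interaction error term). Sphericity of the three-level
factor is checked with Mauchly's test on orthonormal-contrast covariance;
when it rejects at 0.05, the level and interaction degrees of freedom are
scaled by their Greenhouse–Geisser ε̂ (the two-level factor is vacuous,
ε ≡ 1). Both ε̂ and the Mauchly p match `pingouin` to machine precision in
the cross-check tests. When any design cell fails Shapiro–Wilk (p ≤ 0.05), or
is degenerate-constant, the analysis routes wholesale to a rank-based
ANOVA-type statistic (ATS) for the two-within-factor longitudinal design:
overall mid-ranks give relative treatment effects
`p̂ = (R̄ − ½)/N`; the dependence structure is the covariance of the subject
rank vectors; the ATS uses the Box approximation with an `F(f̂, ∞)`
reference (equivalently χ²(f̂)/f̂). The ATS degrees-of-freedom variant is the
ATS (not the Wald-type statistic); under null simulations both branches
reject at 0.047–0.053 at nominal 0.05 (n = 20, 2000 replicates), inside the
0.035–0.065 acceptance band.

**Relative reliability.** ICC(3,1), the two-way mixed, consistency,
single-measures form: `(MS_R − MS_E)/(MS_R + (k−1)·MS_E)`, `k = 2`. The 95%
CI uses the exact F-bound construction
(`F_obs/F_{1−α/2;n−1,(n−1)(k−1)}` and its mirror). Bands are left-closed:
poor < 0.5 ≤ fair < 0.75 ≤ good < 0.9 ≤ excellent. A retest column equal to
the test column (or differing by a constant) yields ICC = 1, as consistency
requires. Zero total variance raises an undefined-ICC error.

**Absolute reliability.** `SEM = SD_pooled · √(1 − ICC)` with `SD_pooled`
the root mean of the two occasions' variances — the "standard deviation of
both measurements" reading; a literal standard error of the mean would not
reproduce the `SDD% = 2.772 · SEM%` pairing that the SEM/SDD framework
implies. `SDD = 1.96·√2·SEM`. Percent forms divide by the combined mean of
all values from both occasions in that condition. Conditions with fewer than
3 complete pairs are flagged not-estimable; missing/incomplete subjects are
dropped per condition (pairwise complete), so per-condition n may vary by
game. No multiplicity correction is applied across the metric × game × level
grid; Bonferroni applies only within the post-hoc pairwise tests.

## Validity

A metric/game is eligible only when ICC(3,1) ≥ 0.5 (inclusive) at *all
three* levels. Given eligibility, a significant level main effect
(p ≤ 0.05, two-sided throughout) and a non-significant timepoint × level
interaction, the three level pairs are compared on per-subject means over
timepoints: paired t-tests (parametric branch) or Wilcoxon signed-rank
(nonparametric branch; exact null distribution up to 25 non-zero pairs
without ties, tie/continuity-corrected normal approximation otherwise;
zero differences dropped by convention). Raw p-values are Bonferroni-scaled
by 3 and capped at 1. Post-hocs are *refused*, never silently computed, when
any gate fails.

**Effect sizes.** The nonparametric branch reports the standard
`r = |Z|/√N` with `N` the number of observations in the comparison (2 ×
pairs), bounded by 1. The parametric branch reports `r = |t|/√n_pairs`,
which can exceed 1; this t-based convention is the one consistent with
published repeated-measures effect sizes above 1 in this literature, and the
branch is labelled in the output so the two scales are never mixed silently.
Bands are left-closed at 0.1/0.3/0.5, with r < 0.1 reported as negligible.

## Sample-size planning

`sample_size_icc(ρ₀, w, conf, assurance, k)` starts from Bonett's closed
form `n₀ = 8z²(1−ρ₀)²(1+(k−1)ρ₀)²/(k(k−1)w²) + 1` and inflates n until the
CI width achieved at the `(1 − assurance)` quantile of the estimator's exact
sampling distribution (`F_obs ∼ θ·F(n−1,(n−1)(k−1))`,
`θ = (1+(k−1)ρ₀)/(1−ρ₀)`) is at most `w`. The width is evaluated with the
Fisher-transformation interval for the consistency ICC — for `k = 2` the
classic `atanh` interval of a paired correlation with SE `1/√(n−3)`. At 50%
assurance the quantile is the *median* estimate, which equals ρ₀ exactly for
k = 2 (the median of `F(d, d)` is 1), so the criterion reads "the
median-case interval meets the target width". At ρ₀ = 0.75, w = 0.3, 95%
confidence, 50% assurance, k = 2 the routine returns n = 38. The floor of
the search is n = 4 (the Fisher SE needs n > 3).

## Synthetic cohorts

`generate_cohort` draws subject baselines `∼ N(μ_RR, σ_b²)` (defaults
850 ± 80 ms, an on-task older-adult regime) and, per condition × occasion, a
latent mean `baseline + level_shift + ε_occ` with
`σ_occ = σ_b·√((1−ICC)/ICC)` so the intraclass correlation of the latent
condition means equals `true_icc` *analytically* (default 0.85, the
good-reliability regime). Demand effects default to 0/−60/−120 ms on mean RR
(vagal withdrawal shortens RR; monotonicity is enforced) and 40/30/20 ms on
the respiratory-band amplitude. Each recording accumulates beats
sequentially: a 0.25 Hz respiratory sinusoid, a 0.1 Hz oscillation (25 ms),
a slow 0.005 Hz drift (20 ms), and white beat-to-beat noise (20 ms SD),
floored at 250 ms. The occasion noise acts on the latent condition mean, not
per beat, so recovery targets are exact; per-beat noise adds a small known
attenuation of estimated ICCs (windowed means average ~70 beats, shrinking
its contribution by that factor). Deterministic sinusoids rather than an
integral-pulse-frequency model keep band powers in closed form (`A²/2`) for
oracle checks; an IPFM mode is out of scope. TLX subscores are truncated
discrete draws with level-shifted means (6/10/14 per subscale, SD 3) — only
their ordering and routing behaviour matter downstream. Artifacts are
injected at a configurable rate (missed = merge, extra = split,
ectopic = 20–40% timing shift), at least 3 beats apart, with truth indices
serialized. Everything is reproducible bit-for-bit from the single seed.

`identity_retest=True` copies each test recording as its retest — the
degenerate cohort for which the entire analysis must return ICC = 1 and
SEM% = 0 everywhere. `signals=False` (summary mode) writes the latent
condition means directly into the session table; replicate-heavy studies
(e.g. 100-cohort ICC recovery at n = 43) use this mode so they run in
seconds while exercising the identical reliability code path.

What the generator does **not** emulate: respiratory frequency variability
and RSA amplitude dependence on breathing depth, heteroscedastic or
autocorrelated occasion noise, circadian effects, drop-out mechanisms
correlated with signal quality, and real sensor error modes (baseline
wander, connector dropouts). Passing tests therefore demonstrate that the
*statistical machinery* recovers known structure under the stated model —
not that any particular physiological effect size holds in real cohorts.

## Numerical choices and degenerate inputs

- Interpolation is cubic spline wherever a tachogram is resampled; linear
  when mapping grid residuals back to beats (the residual is band-limited by
  the 4 Hz grid).
- The trend solve uses a sparse Cholesky-backed `spsolve`; a dense direct
  solve of the same system is the test oracle (agreement to 1e−8).
- ICC with `MS_E = 0` but `MS_R > 0` returns (1, 1, 1) rather than dividing
  by zero; zero total variance is an error.
- Shapiro–Wilk on a constant cell is undefined → conservative nonparametric
  routing.
- Wilcoxon with all-zero differences returns p = 1, r = 0.
- `segment_last` on a too-short recording raises an insufficient-data error
  carrying the available duration.
- Runtime scaling: the default end-to-end check uses a 43-subject × 5-game
  cohort (1290 recordings of 90 s), which the pipeline processes in a few
  seconds; replicate studies use summary mode as above.

## Known limitations

- The beat-artifact detector is a faithful member of the published
  quartile-deviation family but not a line-by-line reimplementation of any
  proprietary algorithm; only the corrected fraction feeds the gate, so
  subtype confusions (missed vs misaligned) do not propagate.
- The spectral estimator (Welch at 4 Hz) is a documented convention choice;
  autoregressive spectra would give smoother 60-s HF estimates, and HF/HFnu
  from 60-s windows remain the least stable metrics (visible in the
  end-to-end example, where spectral metrics show poor reliability while mRR
  and the PNS-Index do well).
- The parametric effect-size convention `|t|/√n` and the nonparametric
  `|Z|/√N` live on different scales by design; compare bands, not raw values,
  across branches.
- Sphericity handling applies per-effect ε̂ to the level and interaction
  terms only when Mauchly rejects — the always-correct option (always apply
  ε̂) is a one-line change but was not the analysis being mirrored.
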