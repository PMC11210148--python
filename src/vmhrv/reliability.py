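"""Three-level test-retest reliability analysis and ICC-precision planning.

Level 1 — systematic error: a balanced two-way within-subject ANOVA
(timepoint x demand level) with Mauchly's sphericity test and
Greenhouse-Geisser correction, or, when any design cell fails
Shapiro-Wilk normality, a rank-based ANOVA-type statistic (ATS) for the
two-within-factor longitudinal design.

Level 2 — relative reliability: the two-way mixed, consistency,
single-measures intraclass correlation ICC(3,1) with its exact F-bound
95% confidence interval, banded poor (< 0.5), fair [0.5, 0.75),
good [0.75, 0.9), excellent (>= 0.9).

Level 3 — absolute reliability: SEM = SD * sqrt(1 - ICC) with SD the
pooled standard deviation over both occasions, SDD = SEM * 1.96 * sqrt(2),
both also mean-normalized (SEM%, SDD%) against the combined mean of both
measurements.

Planning: minimum sample size so that the ICC confidence interval
achieves a desired width with a stated assurance probability, starting
from Bonett's closed form and inflating until the assurance holds under
the estimator's exact sampling distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateRanksError,
    DesignError,
    InsufficientDataError,
    UndefinedMetricError,
)
from .rr_ingest import SessionTable

__all__ = [
    "PairedMeasurements",
    "ReliabilityResult",
    "RmAnovaResult",
    "AtsResult",
    "icc_3_1",
    "classify_icc",
    "sem_abs",
    "sdd_abs",
    "normalize_pct",
    "rm_anova_2way",
    "rank_ats_anova",
    "route_test",
    "sample_size_icc",
    "reliability_report",
]

SDD_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class PairedMeasurements:
    """n_subjects x 2 (test, retest) values for one metric x condition."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("values must be an (n, 2) matrix")
        if np.isnan(v).any():
            raise ValueError("incomplete pairs must be dropped upstream")
        if v.shape[0] < 3:
            raise InsufficientDataError(
                f"need >= 3 complete pairs, got {v.shape[0]}", available=v.shape[0]
            )
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())


@dataclass
class RmAnovaResult:
    F_time: float
    p_time: float
    F_level: float
    p_level: float
    F_interaction: float
    p_interaction: float
    gg_epsilon: float
    mauchly_p: float
    gg_applied: bool


@dataclass
class AtsResult:
    ats_time: float
    p_time: float
    ats_level: float
    p_level: float
    ats_interaction: float
    p_interaction: float


@dataclass
class ReliabilityResult:
    """One condition's row of the reliability grid."""

    metric: str
    phase: object
    game: str
    level: str
    n: int
    icc: float = np.nan
    icc_ci: tuple = (np.nan, np.nan)
    icc_band: str = ""
    sem: float = np.nan
    sem_pct: float = np.nan
    sdd: float = np.nan
    sdd_pct: float = np.nan
    anova_time_stat: float = np.nan
    anova_time_p: float = np.nan
    gg_epsilon: float = np.nan
    used_nonparametric: bool = False
    descriptives: dict = field(default_factory=dict)
    estimable: bool = True
    reason: str = ""


# ---------------------------------------------------------------------------
# ICC(3,1) and absolute reliability


def _two_way_ms(values: np.ndarray):
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = values - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_error


def icc_3_1(d: PairedMeasurements, conf: float = 0.95):
    """ICC(3,1): two-way mixed, single measures, consistency; exact F CI.

    Returns ``(icc, ci_low, ci_high)``.  Raises
    :class:`UndefinedMetricError` on zero total variance.
    """
    v = d.values
    n, k = v.shape
    ms_rows, _, ms_error = _two_way_ms(v)
    if ms_rows + ms_error == 0:
        raise UndefinedMetricError("zero total variance; ICC undefined")
    icc = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
    a = 1 - conf
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_error == 0:
        return float(icc), 1.0, 1.0
    fobs = ms_rows / ms_error
    fu = stats.f.ppf(1 - a / 2, df1, df2)
    fl = stats.f.ppf(1 - a / 2, df2, df1)
    f_low = fobs / fu
    f_up = fobs * fl
    lo = (f_low - 1) / (f_low + k - 1)
    hi = (f_up - 1) / (f_up + k - 1)
    return float(icc), float(lo), float(hi)


def classify_icc(icc: float) -> str:
    """poor < 0.5 <= fair < 0.75 <= good < 0.9 <= excellent (left-closed)."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "fair"
    if icc < 0.9:
        return "good"
    return "excellent"


def sem_abs(d: PairedMeasurements, icc: float) -> float:
    """SEM = pooled SD over both occasions * sqrt(1 - ICC)."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    v = d.values
    pooled_sd = math.sqrt(np.mean(np.var(v, axis=0, ddof=1)))
    return float(pooled_sd * math.sqrt(1 - icc))


def sdd_abs(sem: float) -> float:
    """Smallest detectable difference: SEM * 1.96 * sqrt(2)."""
    if sem < 0:
        raise ValueError("SEM must be >= 0")
    return float(sem * SDD_FACTOR)


def normalize_pct(x: float, grand_mean: float) -> float:
    """Mean-normalized percentage: 100 * x / grand_mean."""
    if grand_mean == 0:
        raise UndefinedMetricError("grand mean is zero; percentage undefined")
    return 100.0 * x / grand_mean


# ---------------------------------------------------------------------------
# Two-way within-subject ANOVA with sphericity handling


def _as_cube(a) -> np.ndarray:
    """Coerce long-format rows or an (n, a, b) array to a design cube."""
    if isinstance(a, np.ndarray):
        if a.ndim != 3:
            raise DesignError("design array must be (subjects, A levels, B levels)")
        if np.isnan(a).any():
            raise DesignError("design is incomplete (NaN cells)")
        return a
    df = a if isinstance(a, pd.DataFrame) else pd.DataFrame(a)
    required = {"subject", "timepoint", "level", "value"}
    if not required <= set(df.columns):
        raise DesignError(f"long design needs columns {sorted(required)}")
    piv = df.pivot_table(
        index="subject", columns=["timepoint", "level"], values="value", aggfunc="first"
    )
    tps = sorted(df["timepoint"].unique())
    lvs = list(pd.unique(df["level"]))
    cube = np.empty((piv.shape[0], len(tps), len(lvs)))
    for i, tp in enumerate(tps):
        for j, lv in enumerate(lvs):
            if (tp, lv) not in piv.columns:
                raise DesignError(f"missing cell ({tp}, {lv})")
            cube[:, i, j] = piv[(tp, lv)].to_numpy()
    if np.isnan(cube).any():
        raise DesignError("unbalanced design: incomplete subjects present")
    return cube


def _orthonormal_contrast(m: int) -> np.ndarray:
    """(m-1) x m orthonormal rows spanning the contrast space."""
    h = np.zeros((m - 1, m))
    for i in range(1, m):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def _gg_epsilon(y_eff: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from orthonormal-contrast covariance."""
    d = y_eff.shape[1]
    if d <= 1:
        return 1.0
    s = np.cov(y_eff, rowvar=False)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    denom = d * np.trace(s @ s)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr**2 / denom, 1.0 / d)))


def _mauchly_p(y_eff: np.ndarray, n: int) -> float:
    """Mauchly's sphericity test on contrast-transformed data."""
    d = y_eff.shape[1]
    if d <= 1:
        return np.nan
    s = np.atleast_2d(np.cov(y_eff, rowvar=False))
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 1e-12):
        return 0.0
    w = np.prod(eig) / (np.mean(eig) ** d)
    c = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * c * math.log(w)
    dof = d * (d + 1) // 2 - 1
    return float(stats.chi2.sf(chi2, dof))


def rm_anova_2way(a, alpha_sphericity: float = 0.05) -> RmAnovaResult:
    """Balanced two-way (timepoint x level) within-subject ANOVA.

    Accepts an (n_subjects, n_timepoints, n_levels) array or long rows
    with columns subject/timepoint/level/value.  When Mauchly's test on
    the multi-level factor rejects at ``alpha_sphericity``, the level and
    interaction degrees of freedom are scaled by their Greenhouse-Geisser
    epsilon estimates (the 2-level factor is sphericity-vacuous).
    """
    y = _as_cube(a)
    n, na, nb = y.shape
    if n < 2:
        raise DesignError("need >= 2 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * nb * np.sum((m_a - grand) ** 2)
    ss_b = n * na * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df_a, df_b, df_ab = na - 1, nb - 1, (na - 1) * (nb - 1)
    df_as, df_bs, df_abs = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / (ss_as / df_as)
        f_b = (ss_b / df_b) / (ss_bs / df_bs)
        f_ab = (ss_ab / df_ab) / (ss_abs / df_abs)

    # sphericity on the multi-level factor (B): contrast the subject x level means
    cb = _orthonormal_contrast(nb)
    yb = m_sb @ cb.T
    eps_b = _gg_epsilon(yb)
    mauchly = _mauchly_p(yb, n)
    # interaction contrasts
    ca = _orthonormal_contrast(na)
    yab = np.einsum("pi,nij,qj->npq", ca, y, cb).reshape(n, -1)
    eps_ab = _gg_epsilon(yab)

    apply_gg = nb > 2 and not np.isnan(mauchly) and mauchly <= alpha_sphericity
    e_b = eps_b if apply_gg else 1.0
    e_ab = eps_ab if apply_gg else 1.0
    p_a = float(stats.f.sf(f_a, df_a, df_as))
    p_b = float(stats.f.sf(f_b, e_b * df_b, e_b * df_bs))
    p_ab = float(stats.f.sf(f_ab, e_ab * df_ab, e_ab * df_abs))
    return RmAnovaResult(
        F_time=float(f_a),
        p_time=p_a,
        F_level=float(f_b),
        p_level=p_b,
        F_interaction=float(f_ab),
        p_interaction=p_ab,
        gg_epsilon=float(eps_b) if nb > 2 else 1.0,
        mauchly_p=float(mauchly) if nb > 2 else np.nan,
        gg_applied=bool(apply_gg),
    )


# ---------------------------------------------------------------------------
# Rank-based ANOVA-type statistic (two within-subject factors)


def _ats_effect(phat, vhat, contrast, n):
    t = contrast.T @ np.linalg.pinv(contrast @ contrast.T) @ contrast
    tv = t @ vhat
    trace_tv = np.trace(tv)
    if trace_tv <= 0:
        return np.nan, np.nan
    stat = n * phat @ t @ phat / trace_tv
    f_hat = trace_tv**2 / np.trace(tv @ tv)
    # F(f_hat, inf) reference == chi-square(f_hat) / f_hat
    p = float(stats.chi2.sf(stat * f_hat, f_hat))
    return float(stat), p


def rank_ats_anova(a) -> AtsResult:
    """Rank-based ANOVA-type statistics for a (timepoint x level) design.

    Mid-ranks over all observations yield relative treatment effects per
    cell; the ATS uses the Box approximation with F(f_hat, inf)
    reference, with the covariance of the subject rank vectors supplying
    the dependence structure.
    """
    y = _as_cube(a)
    n, na, nb = y.shape
    if n < 2:
        raise DegenerateRanksError("rank ANOVA needs >= 2 subjects")
    flat = y.reshape(n, na * nb)
    if np.ptp(flat) == 0:
        raise DegenerateRanksError("all values tied; ranks degenerate")
    big = stats.rankdata(flat.ravel()).reshape(n, na * nb)
    ntot = n * na * nb
    phat = (big.mean(axis=0) - 0.5) / ntot
    # covariance of sqrt(n) * phat, estimated from the subject rank vectors
    vhat = np.cov(big, rowvar=False) / ntot**2

    ident = np.eye
    ja, jb = np.ones((na, na)) / na, np.ones((nb, nb)) / nb
    pa, pb = ident(na) - ja, ident(nb) - jb
    one_a, one_b = np.ones((1, na)) / na, np.ones((1, nb)) / nb
    c_time = np.kron(pa, one_b)
    c_level = np.kron(one_a, pb)
    c_inter = np.kron(pa, pb)

    s_t, p_t = _ats_effect(phat, vhat, c_time, n)
    s_l, p_l = _ats_effect(phat, vhat, c_level, n)
    s_i, p_i = _ats_effect(phat, vhat, c_inter, n)
    return AtsResult(s_t, p_t, s_l, p_l, s_i, p_i)


def route_test(cells, alpha: float = 0.05) -> str:
    """Choose the analysis branch via per-cell Shapiro-Wilk normality.

    ``cells`` is an iterable of samples (one per design cell).  Any cell
    with p <= alpha — or a degenerate constant cell, where the test is
    undefined — routes to the nonparametric branch.
    """
    for cell in cells:
        x = np.asarray(cell, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 3 or np.ptp(x) == 0:
            return "nonparametric"
        if stats.shapiro(x).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# ICC-precision sample size


def _fisher_ci_width(rho: float, n: int, k: int, conf: float) -> float:
    """Width of the Fisher-transformation CI for the consistency ICC.

    z = 0.5 ln((1+(k-1)rho)/(1-rho)) with SE sqrt(k / (2(k-1)(n-3)));
    for k = 2 this is the classic atanh interval of a paired correlation.
    """
    z = 0.5 * math.log((1 + (k - 1) * rho) / (1 - rho))
    se = math.sqrt(k / (2.0 * (k - 1) * (n - 3)))
    zcrit = stats.norm.ppf(1 - (1 - conf) / 2)
    lo, hi = z - zcrit * se, z + zcrit * se
    back = lambda zz: (math.exp(2 * zz) - 1) / (math.exp(2 * zz) + k - 1)
    return back(hi) - back(lo)


def sample_size_icc(
    rho0: float,
    width: float,
    conf: float = 0.95,
    assurance: float = 0.5,
    k: int = 2,
    n_max: int = 100000,
) -> int:
    """Minimum n for an ICC CI of desired width with a given assurance.

    Starts from Bonett's closed form
    ``8 z^2 (1-rho)^2 (1+(k-1)rho)^2 / (k (k-1) w^2) + 1`` and inflates n
    until the CI width achieved at the (1 - assurance) quantile of the
    estimator's exact F sampling distribution is at most ``width``.  At
    50% assurance that quantile is the median estimate, which equals
    ``rho0`` exactly for k = 2 (the median of F(n-1, n-1) is 1), so the
    criterion is "the median-case interval meets the target width".
    """
    if not 0 < rho0 < 1:
        raise ValueError("rho0 must be in (0, 1)")
    if not 0 < width < 2:
        raise ValueError("width must be in (0, 2)")
    if not 0 < conf < 1 or not 0 < assurance < 1:
        raise ValueError("conf and assurance must be in (0, 1)")
    if k < 2:
        raise ValueError("need k >= 2 measurements")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    n0 = 8 * z**2 * (1 - rho0) ** 2 * (1 + (k - 1) * rho0) ** 2 / (
        k * (k - 1) * width**2
    ) + 1
    n = max(4, math.ceil(n0 - 1e-9))
    theta = (1 + (k - 1) * rho0) / (1 - rho0)
    while n <= n_max:
        fq = theta * stats.f.ppf(1 - assurance, n - 1, (n - 1) * (k - 1))
        rho_q = (fq - 1) / (fq + k - 1)
        if rho_q <= 0:
            rho_q = 1e-9
        if _fisher_ci_width(rho_q, n, k, conf) <= width + 1e-12:
            return n
        n += 1
    raise ValueError("no feasible n below n_max for the requested precision")


# ---------------------------------------------------------------------------
# The full reliability grid


def _descriptives(x: np.ndarray, parametric: bool) -> dict:
    x = np.asarray(x, dtype=float)
    if parametric:
        return {"center": float(np.mean(x)), "spread": float(np.std(x, ddof=1)),
                "style": "mean±SD"}
    q1, q3 = np.percentile(x, [25, 75])
    return {"center": float(np.median(x)), "spread": float(q3 - q1),
            "style": "median(IQR)"}


def reliability_report(
    table: SessionTable, metric: str, alpha: float = 0.05
) -> list[ReliabilityResult]:
    """Assemble the per-(phase x game x level) reliability grid for one metric.

    For each game a 2 (timepoint) x 3 (level) within-subject design is
    built from quality-passed complete cases; normality routing selects
    the parametric RM-ANOVA or the rank ATS; each level contributes
    ICC(3,1) + CI + band and SEM/SEM%/SDD/SDD%.  Conditions with fewer
    than 3 complete pairs are flagged not estimable.
    """
    results: list[ReliabilityResult] = []
    df = table.analysis_rows()
    for phase in sorted(df["phase"].dropna().unique()):
        for game in [g for g in SessionTable.GAMES if g in set(df["game"])]:
            pairs = {}
            for level in SessionTable.ANALYSIS_LEVELS:
                wide = table.complete_pairs(metric, phase, game, level)
                pairs[level] = wide
            # joint design needs subjects complete in all 6 cells
            common = None
            for wide in pairs.values():
                idx = set(wide.index)
                common = idx if common is None else common & idx
            common = sorted(common) if common else []
            anova = None
            used_np = False
            if len(common) >= 3:
                cube = np.stack(
                    [
                        np.stack(
                            [
                                pairs[lv].loc[common, tp].to_numpy()
                                for lv in SessionTable.ANALYSIS_LEVELS
                            ],
                            axis=1,
                        )
                        for tp in SessionTable.TIMEPOINTS
                    ],
                    axis=1,
                )  # (n, 2, 3)
                cells = [cube[:, i, j] for i in range(2) for j in range(3)]
                branch = route_test(cells, alpha)
                used_np = branch == "nonparametric"
                try:
                    anova = (
                        rank_ats_anova(cube) if used_np else rm_anova_2way(cube)
                    )
                except (DegenerateRanksError, DesignError):
                    anova = None
            for level in SessionTable.ANALYSIS_LEVELS:
                wide = pairs[level]
                res = ReliabilityResult(
                    metric=metric, phase=phase, game=game, level=level, n=len(wide)
                )
                if len(wide) < 3:
                    res.estimable = False
                    res.reason = f"n={len(wide)} complete pairs < 3"
                    results.append(res)
                    continue
                d = PairedMeasurements(wide.to_numpy())
                try:
                    icc, lo, hi = icc_3_1(d)
                except UndefinedMetricError:
                    res.estimable = False
                    res.reason = "zero total variance"
                    results.append(res)
                    continue
                res.icc, res.icc_ci = icc, (lo, hi)
                res.icc_band = classify_icc(min(icc, 1.0))
                res.sem = sem_abs(d, min(icc, 1.0))
                res.sdd = sdd_abs(res.sem)
                try:
                    res.sem_pct = normalize_pct(res.sem, d.grand_mean)
                    res.sdd_pct = normalize_pct(res.sdd, d.grand_mean)
                except UndefinedMetricError:
                    pass
                res.used_nonparametric = used_np
                res.descriptives = _descriptives(d.values.ravel(), not used_np)
                if isinstance(anova, RmAnovaResult):
                    res.anova_time_stat = anova.F_time
                    res.anova_time_p = anova.p_time
                    res.gg_epsilon = anova.gg_epsilon
                elif isinstance(anova, AtsResult):
                    res.anova_time_stat = anova.ats_time
                    res.anova_time_p = anova.p_time
                results.append(res)
    return results


def reliability_frame(results: list[ReliabilityResult]) -> pd.DataFrame:
    """Flatten :func:`reliability_report` output to a tabular grid."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric,
                "phase": r.phase,
                "game": r.game,
                "level": r.level,
                "n": r.n,
                "estimable": r.estimable,
                "icc": r.icc,
                "icc_ci_low": r.icc_ci[0],
                "icc_ci_high": r.icc_ci[1],
                "icc_band": r.icc_band,
                "sem": r.sem,
                "sem_pct": r.sem_pct,
                "sdd": r.sdd,
                "sdd_pct": r.sdd_pct,
                "anova_time_stat": r.anova_time_stat,
                "anova_time_p": r.anova_time_p,
                "gg_epsilon": r.gg_epsilon,
                "used_nonparametric": r.used_nonparametric,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)
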