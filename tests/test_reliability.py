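"""ICC(3,1), SEM/SDD, ANOVA branches, routing, and sample-size planning."""

import numpy as np
import pandas as pd
import pytest

from vmhrv import (
    CohortConfig,
    PairedMeasurements,
    UndefinedMetricError,
    classify_icc,
    generate_cohort,
    icc_3_1,
    normalize_pct,
    rank_ats_anova,
    reliability_report,
    rm_anova_2way,
    route_test,
    sample_size_icc,
    sdd_abs,
    sem_abs,
)
from vmhrv.errors import DegenerateRanksError, DesignError
from vmhrv.reliability import SDD_FACTOR


def brute_force_icc31(values):
    """Hand-expanded two-way mean-squares decomposition (independent oracle)."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = v.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (v[i].sum() / k - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (v[:, j].sum() / n - grand) ** 2
    ss_tot = ((v - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc:
    def test_identical_columns_give_one(self):
        v = np.column_stack([np.arange(5.0), np.arange(5.0)])
        icc, lo, hi = icc_3_1(PairedMeasurements(v))
        assert icc == 1.0 and lo == 1.0 and hi == 1.0

    def test_additive_shift_ignored_by_consistency_form(self):
        v = np.column_stack([np.arange(5.0), np.arange(5.0) + 3.7])
        icc, _, _ = icc_3_1(PairedMeasurements(v))
        assert icc == pytest.approx(1.0)

    def test_known_4x2_matrix_matches_oracle(self):
        v = np.array([[1.0, 2], [3, 4], [5, 6], [7, 8]])
        icc, _, _ = icc_3_1(PairedMeasurements(v))
        assert icc == pytest.approx(brute_force_icc31(v), abs=1e-12)

    def test_oracle_equivalence_on_random_matrices(self, rng):
        # 100 random 5x2 instances against the hand-expanded decomposition
        for _ in range(100):
            v = rng.normal(0, 1, (5, 2)) + rng.normal(0, 1, (5, 1))
            icc, _, _ = icc_3_1(PairedMeasurements(v))
            assert icc == pytest.approx(brute_force_icc31(v), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        v = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1.5, (12, 1))
        icc, lo, hi = icc_3_1(PairedMeasurements(v))
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 2),
                "rater": np.tile(["t", "r"], 12),
                "y": v.ravel(),
            }
        )
        tab = pg.intraclass_corr(df, "subj", "rater", "y").set_index("Type")
        assert icc == pytest.approx(float(tab.loc["ICC(C,1)", "ICC"]), abs=1e-9)
        ci = tab.loc["ICC(C,1)", "CI95"]
        assert lo == pytest.approx(ci[0], abs=0.01)
        assert hi == pytest.approx(ci[1], abs=0.01)

    def test_joint_rescaling_invariance(self, rng):
        v = rng.normal(0, 1, (8, 2)) + rng.normal(0, 1, (8, 1))
        a = icc_3_1(PairedMeasurements(v))[0]
        b = icc_3_1(PairedMeasurements(v * 42.0))[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            icc_3_1(PairedMeasurements(np.full((5, 2), 7.0)))

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            v = rng.normal(0, 1, (10, 2)) + rng.normal(0, 1, (10, 1))
            icc, lo, hi = icc_3_1(PairedMeasurements(v))
            assert lo <= icc <= hi


class TestBandsAndAbsolute:
    @pytest.mark.parametrize(
        "icc,band",
        [(0.49, "poor"), (0.5, "fair"), (0.74, "fair"), (0.75, "good"),
         (0.76, "good"), (0.89, "good"), (0.9, "excellent"), (1.0, "excellent")],
    )
    def test_icc_bands_left_closed(self, icc, band):
        assert classify_icc(icc) == band

    def test_sem_zero_at_perfect_icc(self, rng):
        v = rng.normal(0, 10, (6, 2))
        assert sem_abs(PairedMeasurements(v), 1.0) == 0.0

    def test_sem_formula(self):
        # pooled SD 10 by construction, icc 0.75 -> 5.0
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        x = (x - x.mean()) / x.std(ddof=1) * 10.0
        v = np.column_stack([x, x])
        d = PairedMeasurements(v)
        assert sem_abs(d, 0.75) == pytest.approx(5.0)
        assert sem_abs(d, 0.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("sem,expected", [(0, 0), (10, 27.718), (5, 13.859)])
    def test_sdd_factor(self, sem, expected):
        assert sdd_abs(sem) == pytest.approx(expected, abs=2e-3)
        assert SDD_FACTOR == pytest.approx(1.96 * np.sqrt(2))

    def test_normalize_pct(self):
        assert normalize_pct(5, 50) == 10.0
        assert normalize_pct(0, 50) == 0.0
        with pytest.raises(UndefinedMetricError):
            normalize_pct(5, 0)


class TestRmAnova:
    def test_matches_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (12, 2, 3)) + rng.normal(0, 1, (12, 1, 1))
        rows = [
            {"subject": i, "time": tp, "level": lv, "value": y[i, j, k]}
            for i in range(12)
            for j, tp in enumerate(["test", "retest"])
            for k, lv in enumerate(["e", "c", "x"])
        ]
        tab = pg.rm_anova(
            data=pd.DataFrame(rows), dv="value", within=["time", "level"],
            subject="subject", correction=True, detailed=True,
        ).set_index("Source")
        r = rm_anova_2way(y)
        assert r.F_time == pytest.approx(float(tab.loc["time", "F"]), rel=1e-9)
        assert r.F_level == pytest.approx(float(tab.loc["level", "F"]), rel=1e-9)
        assert r.gg_epsilon == pytest.approx(float(tab.loc["level", "eps"]), abs=1e-9)

    def test_two_level_factor_never_corrected(self, rng):
        y = rng.normal(0, 1, (10, 2, 3))
        r = rm_anova_2way(y)
        # the timepoint factor has 2 levels: sphericity is vacuous there
        assert 0 <= r.p_time <= 1

    def test_level_effect_power_grows_with_delta(self, rng):
        hits = {0.25: 0, 1.0: 0}
        for delta in hits:
            for _ in range(60):
                y = (
                    rng.normal(0, 1, (20, 1, 1))
                    + rng.normal(0, 1, (20, 2, 3))
                    + delta * np.array([0.0, 1.0, 2.0])[None, None, :]
                )
                if rm_anova_2way(y).p_level <= 0.05:
                    hits[delta] += 1
        assert hits[1.0] > hits[0.25]

    def test_unbalanced_design_rejected(self):
        rows = pd.DataFrame(
            {
                "subject": [0, 0, 0, 1, 1],
                "timepoint": ["t", "t", "t", "t", "t"],
                "level": ["e", "c", "x", "e", "c"],
                "value": [1.0, 2, 3, 4, 5],
            }
        )
        with pytest.raises(DesignError):
            rm_anova_2way(rows)

    def test_long_format_equals_cube(self, rng):
        y = rng.normal(0, 1, (8, 2, 3))
        rows = [
            {"subject": i, "timepoint": tp, "level": lv, "value": y[i, j, k]}
            for i in range(8)
            for j, tp in enumerate(["a_test", "b_retest"])
            for k, lv in enumerate(["e", "c", "x"])
        ]
        r1 = rm_anova_2way(y)
        r2 = rm_anova_2way(pd.DataFrame(rows))
        assert r1.F_level == pytest.approx(r2.F_level, rel=1e-9)


def permutation_level_p(y, n_perm=5000, seed=0):
    """Within-subject permutation oracle for the level main effect.

    Permutes level assignments within each (subject, timepoint) block and
    compares the between-level dispersion of level means.
    """
    rng = np.random.default_rng(seed)

    def stat(c):
        return np.var(c.mean(axis=(0, 1)))

    obs = stat(y)
    count = 0
    n, a, b = y.shape
    for _ in range(n_perm):
        perm = y.copy()
        for i in range(n):
            for j in range(a):
                perm[i, j] = perm[i, j, rng.permutation(b)]
        if stat(perm) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestRankAts:
    def test_monotone_level_effect_detected_and_matches_permutation(self, rng):
        # deterministic monotone offsets identical for every subject
        y = rng.normal(0, 1, (20, 1, 1)) + rng.normal(0, 0.5, (20, 2, 3))
        y += np.array([0.0, 0.8, 1.6])[None, None, :]
        ats = rank_ats_anova(y)
        assert ats.p_level < 0.05
        assert permutation_level_p(y, n_perm=5000) < 0.05

    def test_null_exchangeable_rejection_rate(self, rng):
        rej = 0
        n_sim = 400
        for _ in range(n_sim):
            y = rng.normal(0, 1, (15, 1, 1)) + rng.normal(0, 1, (15, 2, 3))
            if rank_ats_anova(y).p_level <= 0.05:
                rej += 1
        assert 0.02 <= rej / n_sim <= 0.09

    def test_single_subject_degenerate(self):
        with pytest.raises((DegenerateRanksError, DesignError)):
            rank_ats_anova(np.zeros((1, 2, 3)))

    def test_all_tied_degenerate(self):
        with pytest.raises(DegenerateRanksError):
            rank_ats_anova(np.ones((10, 2, 3)))


class TestRouting:
    def test_normal_cells_route_parametric(self, rng):
        cells = [rng.normal(0, 1, 50) for _ in range(6)]
        assert route_test(cells) == "parametric"

    def test_heavy_skew_routes_nonparametric(self, rng):
        cells = [np.exp(rng.normal(0, 1, 50)) for _ in range(6)]
        assert route_test(cells) == "nonparametric"

    def test_constant_cell_routes_nonparametric(self):
        assert route_test([np.ones(20)]) == "nonparametric"


class TestSampleSize:
    def test_monotone_in_width(self):
        ns = [sample_size_icc(0.75, w) for w in (0.2, 0.3, 0.5, 1.0, 1.9)]
        assert ns == sorted(ns, reverse=True)
        assert ns[-1] >= 4  # the formula floor

    def test_higher_anticipated_icc_needs_fewer(self):
        assert sample_size_icc(0.9, 0.3) < sample_size_icc(0.75, 0.3)

    def test_infeasible_inputs_rejected(self):
        for bad in [(0.0, 0.3), (1.0, 0.3), (0.75, 0.0), (0.75, 2.0)]:
            with pytest.raises(ValueError):
                sample_size_icc(*bad)

    def test_assurance_inflates_n(self):
        assert sample_size_icc(0.75, 0.3, assurance=0.8) > sample_size_icc(
            0.75, 0.3, assurance=0.5
        )


class TestReliabilityReport:
    def test_identity_cohort_perfect_reliability(self):
        # true ICC 1 with zero noise: retest recordings replicate test exactly
        cfg = CohortConfig(
            n_subjects=8, games=("Simple",), true_icc=1.0, noise_sd=0.0, seed=11
        )
        table, _, _ = generate_cohort(cfg, signals=False)
        res = reliability_report(table, "mrr_ms")
        assert len(res) == 3
        for r in res:
            assert r.estimable
            assert r.icc == pytest.approx(1.0)
            assert r.sem_pct == pytest.approx(0.0, abs=1e-9)

    def test_small_condition_flagged_not_estimable(self):
        cfg = CohortConfig(n_subjects=2, games=("Simple",), seed=1)
        table, _, _ = generate_cohort(cfg, signals=False)
        res = reliability_report(table, "mrr_ms")
        assert all(not r.estimable for r in res)

    def test_recovery_of_configured_icc(self):
        # mean estimated ICC over replicate cohorts near the target
        target = 0.8
        est = []
        for rep in range(40):
            cfg = CohortConfig(
                n_subjects=43, games=("Simple",), true_icc=target, seed=100 + rep
            )
            table, _, _ = generate_cohort(cfg, signals=False)
            for r in reliability_report(table, "mrr_ms"):
                est.append(r.icc)
        assert np.mean(est) == pytest.approx(target, abs=0.05)

    def test_sdd_sem_ratio_constant_everywhere(self):
        cfg = CohortConfig(n_subjects=12, games=("Simple", "Tetris"), seed=5)
        table, _, _ = generate_cohort(cfg, signals=False)
        for r in reliability_report(table, "mrr_ms"):
            if r.estimable and r.sem > 0:
                assert r.sdd / r.sem == pytest.approx(SDD_FACTOR, rel=1e-12)
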