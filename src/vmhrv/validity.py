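"""Validity of vm-HRV as an internal-training-load marker.

A metric enters the validity analysis only when its test-retest
reliability is at least fair (ICC(3,1) >= 0.5) at all three demand
levels.  Given a significant level main effect and no significant
timepoint x level interaction, post-hoc pairwise comparisons run over
the three level pairs with Bonferroni correction: paired t-tests on the
parametric branch, Wilcoxon signed-rank tests (exact null up to 25
pairs, tie/continuity-corrected normal approximation above) otherwise.

Effect sizes: the nonparametric branch uses the standard r = |Z|/sqrt(N)
with N the number of observations in the comparison; the parametric
branch uses r = |t|/sqrt(n_pairs), which is not bounded by 1 and
reproduces the scale of t-based effect sizes reported in repeated-
measures exergaming work.  Bands: negligible < 0.1 <= small < 0.3 <=
medium < 0.5 <= large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GateRefusalError
from .reliability import (
    RmAnovaResult,
    rank_ats_anova,
    rm_anova_2way,
    route_test,
)
from .rr_ingest import SessionTable

__all__ = [
    "ValidityResult",
    "eligibility_gate",
    "posthoc_pairwise",
    "effect_size_r",
    "classify_r",
    "validity_report",
]

LEVEL_PAIRS = (
    ("easy", "challenging"),
    ("easy", "excessive"),
    ("challenging", "excessive"),
)


@dataclass
class ValidityResult:
    metric: str
    phase: object
    game: str
    eligible: bool
    gate_reason: str = ""
    F_level: float = np.nan
    p_level: float = np.nan
    interaction_p: float = np.nan
    used_nonparametric: bool = False
    #: (level_a, level_b) -> {"p_raw", "p_adj", "r", "band", "stat"}
    pairwise: dict = field(default_factory=dict)


def eligibility_gate(iccs) -> tuple[bool, str]:
    """True iff every demand level has ICC(3,1) >= 0.5.

    ``iccs`` maps level name -> ICC (or is a 3-sequence in level order).
    Missing or NaN entries fail the gate with a reason.
    """
    if isinstance(iccs, dict):
        vals = [iccs.get(lv) for lv in SessionTable.ANALYSIS_LEVELS]
        names = SessionTable.ANALYSIS_LEVELS
    else:
        vals = list(iccs)
        names = [f"level{i + 1}" for i in range(len(vals))]
    if len(vals) != 3:
        return False, "expected ICCs for exactly 3 levels"
    for name, v in zip(names, vals):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return False, f"missing ICC for {name}"
        if v < 0.5:
            return False, f"ICC {v:.3f} < 0.5 at {name}"
    return True, ""


def effect_size_r(test_stat: float, n: int) -> float:
    """r = |stat| / sqrt(n); ``n`` counts observations (or pairs, t-based)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return abs(test_stat) / math.sqrt(n)


def classify_r(r: float) -> str:
    """negligible < 0.1 <= small < 0.3 <= medium < 0.5 <= large."""
    if r < 0:
        raise ValueError("effect size r must be >= 0")
    if r < 0.1:
        return "negligible"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "medium"
    return "large"


def _wilcoxon_z(d: np.ndarray) -> float:
    """Signed-rank Z from the tie/continuity-corrected normal approximation."""
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    ties = pd.Series(np.abs(d)).value_counts().to_numpy()
    tie_term = np.sum(ties**3 - ties) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 0.0
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    return float((diff - cc) / math.sqrt(sigma2))


def posthoc_pairwise(
    level_values: dict,
    branch: str,
    p_level: float,
    p_interaction: float,
    alpha: float = 0.05,
) -> dict:
    """Bonferroni-corrected pairwise comparisons of the three demand levels.

    ``level_values`` maps level -> per-subject values (arrays aligned on
    the same subjects, typically subject means over timepoints).  Refuses
    with :class:`GateRefusalError` unless the level main effect is
    significant and the interaction is not — post-hocs are never silently
    computed past the gate.
    """
    if math.isnan(p_level) or p_level > alpha:
        raise GateRefusalError(
            f"level main effect not significant (p={p_level:.4g})",
            reason="main_effect",
        )
    if not math.isnan(p_interaction) and p_interaction <= alpha:
        raise GateRefusalError(
            f"significant timepoint x level interaction (p={p_interaction:.4g})",
            reason="interaction",
        )
    m = len(LEVEL_PAIRS)
    out = {}
    for la, lb in LEVEL_PAIRS:
        x = np.asarray(level_values[la], dtype=float)
        y = np.asarray(level_values[lb], dtype=float)
        if x.shape != y.shape:
            raise ValueError("level samples must be subject-aligned")
        n_pairs = x.size
        if branch == "parametric":
            t, p_raw = stats.ttest_rel(x, y)
            r = effect_size_r(float(t), n_pairs)
            stat = float(t)
        else:
            d = x - y
            nz = d[d != 0]
            has_ties = pd.Series(np.abs(nz)).duplicated().any() if nz.size else False
            if nz.size == 0:
                p_raw, stat = 1.0, 0.0
            else:
                method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
                p_raw = float(
                    stats.wilcoxon(nz, method=method, correction=True).pvalue
                )
                stat = _wilcoxon_z(d)
            r = effect_size_r(stat, 2 * n_pairs)
        out[(la, lb)] = {
            "stat": stat,
            "p_raw": float(p_raw),
            "p_adj": min(1.0, m * float(p_raw)),
            "r": r,
            "band": classify_r(r),
            "n_pairs": n_pairs,
        }
    return out


def validity_report(
    table: SessionTable,
    metric: str,
    per_level_iccs: dict,
    alpha: float = 0.05,
) -> list[ValidityResult]:
    """Full validity analysis of one metric across phases and games.

    ``per_level_iccs`` maps (phase, game) -> {level: ICC} from the
    reliability stage.  For eligible conditions the level main effect and
    interaction come from the routed 2x3 within-subject ANOVA; post-hocs
    follow the stated gate.
    """
    results: list[ValidityResult] = []
    df = table.analysis_rows()
    for phase in sorted(df["phase"].dropna().unique()):
        for game in [g for g in SessionTable.GAMES if g in set(df["game"])]:
            eligible, reason = eligibility_gate(
                per_level_iccs.get((phase, game), {})
            )
            res = ValidityResult(
                metric=metric, phase=phase, game=game,
                eligible=eligible, gate_reason=reason,
            )
            if not eligible:
                results.append(res)
                continue
            pairs = {
                lv: table.complete_pairs(metric, phase, game, lv)
                for lv in SessionTable.ANALYSIS_LEVELS
            }
            common = sorted(
                set.intersection(*(set(w.index) for w in pairs.values()))
            )
            if len(common) < 3:
                res.eligible = False
                res.gate_reason = f"only {len(common)} complete subjects"
                results.append(res)
                continue
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
            )
            cells = [cube[:, i, j] for i in range(2) for j in range(3)]
            branch = route_test(cells, alpha)
            res.used_nonparametric = branch == "nonparametric"
            anova = rank_ats_anova(cube) if res.used_nonparametric else rm_anova_2way(cube)
            if isinstance(anova, RmAnovaResult):
                res.F_level, res.p_level = anova.F_level, anova.p_level
                res.interaction_p = anova.p_interaction
            else:
                res.F_level, res.p_level = anova.ats_level, anova.p_level
                res.interaction_p = anova.p_interaction
            level_means = {
                lv: cube[:, :, j].mean(axis=1)
                for j, lv in enumerate(SessionTable.ANALYSIS_LEVELS)
            }
            try:
                res.pairwise = posthoc_pairwise(
                    level_means, branch, res.p_level, res.interaction_p, alpha
                )
            except GateRefusalError:
                res.pairwise = {}
            results.append(res)
    return results


def validity_frame(results: list[ValidityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        base = {
            "metric": r.metric,
            "phase": r.phase,
            "game": r.game,
            "eligible": r.eligible,
            "gate_reason": r.gate_reason,
            "F_level": r.F_level,
            "p_level": r.p_level,
            "interaction_p": r.interaction_p,
            "used_nonparametric": r.used_nonparametric,
        }
        if not r.pairwise:
            rows.append({**base, "comparison": "", "p_adj": np.nan,
                         "r": np.nan, "band": ""})
        for (la, lb), pw in r.pairwise.items():
            rows.append(
                {
                    **base,
                    "comparison": f"{la} vs {lb}",
                    "p_adj": pw["p_adj"],
                    "r": pw["r"],
                    "band": pw["band"],
                }
            )
    return pd.DataFrame(rows)
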