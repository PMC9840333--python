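"""Between-group comparison of band summaries: assumption checks,
one-way ANOVA, and variance-aware post-hoc routing.

The ANOVA is always the classical fixed-effects decomposition (no Welch
substitution); variance heterogeneity only changes the post-hoc method:
Levene p < 0.05 routes to Games-Howell, otherwise Tukey HSD.  No
multiple-testing correction is applied across outcomes — the output
records how many outcomes were tested so users can correct post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupStatsResult",
    "check_assumptions",
    "oneway_anova",
    "posthoc",
    "analyze_outcome",
    "analyze_outcomes",
]

ALPHA = 0.05


@dataclass
class GroupStatsResult:
    outcome: tuple = ()
    group_labels: list[str] = field(default_factory=list)
    group_ns: list[int] = field(default_factory=list)
    shapiro_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")
    F: float = float("nan")
    df_between: int = 0
    df_within: int = 0
    p: float = float("nan")
    significant: bool = False
    posthoc_method: str = ""
    posthoc_rows: pd.DataFrame | None = None


def _as_groups(values_by_group: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float).ravel() for k, v in values_by_group.items()}


def check_assumptions(values_by_group: dict) -> tuple[dict[str, float], float]:
    """Shapiro-Wilk normality p per group and a single Levene p.

    Levene's test uses the group-mean centring (the classical variant).
    Degenerate (zero-variance) groups raise, since both tests are
    undefined there.
    """
    groups = _as_groups(values_by_group)
    for label, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {label!r} has n={len(v)} < 3")
        if np.ptp(v) == 0:
            raise ValueError(f"group {label!r} is constant; normality test undefined")
    shapiro_p = {label: float(sps.shapiro(v).pvalue) for label, v in groups.items()}
    levene_p = float(sps.levene(*groups.values(), center="mean").pvalue)
    return shapiro_p, levene_p


def oneway_anova(values_by_group: dict) -> GroupStatsResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for label, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {label!r} has n={len(v)} < 2")
    all_values = np.concatenate(list(groups.values()))
    grand = all_values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ms_b == 0 else float("inf")
        p = 1.0 if ms_b == 0 else 0.0
    else:
        F = float(ms_b / ms_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return GroupStatsResult(
        group_labels=list(groups),
        group_ns=[len(v) for v in groups.values()],
        F=F,
        df_between=df_b,
        df_within=df_w,
        p=p,
        significant=bool(p < ALPHA),
    )


def posthoc(values_by_group: dict, levene_p: float) -> tuple[str, pd.DataFrame]:
    """Pairwise comparisons, routed by variance homogeneity.

    Tukey HSD when ``levene_p >= 0.05``, Games-Howell otherwise.  Returns
    ``(method_name, table)`` with columns (A, B, diff, p).
    """
    import pingouin as pg

    groups = _as_groups(values_by_group)
    df = pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups), [len(v) for v in groups.values()]),
        }
    )
    if levene_p >= ALPHA:
        method = "tukey"
        table = pg.pairwise_tukey(data=df, dv="value", between="group")
        table = table.rename(columns={"p_tukey": "p"})
    else:
        method = "games-howell"
        table = pg.pairwise_gameshowell(data=df, dv="value", between="group")
        table = table.rename(columns={"pval": "p"})
    return method, table[["A", "B", "diff", "p"]].copy()


def analyze_outcome(values_by_group: dict, outcome: tuple = ()) -> GroupStatsResult:
    """Full chain for one outcome: assumptions, ANOVA, routed post-hoc."""
    shapiro_p, levene_p = check_assumptions(values_by_group)
    result = oneway_anova(values_by_group)
    result.outcome = outcome
    result.shapiro_p = shapiro_p
    result.levene_p = levene_p
    if len(values_by_group) >= 3:
        result.posthoc_method, result.posthoc_rows = posthoc(values_by_group, levene_p)
    return result


def analyze_outcomes(summaries: pd.DataFrame, group_order: list[str] | None = None) -> pd.DataFrame:
    """Run the chain over every (roi, band, measure) outcome of a
    band-summary table and return one row per outcome.

    The returned frame carries ``n_outcomes_tested`` so downstream users
    can apply their own multiplicity correction.
    """
    required = {"subject_id", "group", "roi", "band", "measure", "value"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    rows = []
    outcomes = summaries.groupby(["roi", "band", "measure"], sort=False)
    n_outcomes = len(outcomes)
    for (roi, band, measure), sub in outcomes:
        sub = sub.dropna(subset=["value"])
        labels = group_order or sorted(sub["group"].unique())
        values_by_group = {
            g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in labels
        }
        res = analyze_outcome(values_by_group, outcome=(roi, band, measure))
        rows.append(
            {
                "roi": roi,
                "band": band,
                "measure": measure,
                "groups": ",".join(res.group_labels),
                "ns": ",".join(map(str, res.group_ns)),
                "levene_p": res.levene_p,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "significant": res.significant,
                "posthoc_method": res.posthoc_method,
                "n_outcomes_tested": n_outcomes,
            }
        )
    return pd.DataFrame(rows)
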