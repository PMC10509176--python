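"""Assumption-routed group comparisons and symptom-severity correlations.

Each feature is compared between a patient group and controls as a percent
change from the control mean.  The test is routed by its assumptions:
Shapiro-Wilk normality per group (any failure -> Mann-Whitney U), then
Levene's variance test (failure -> Welch ANOVA), else a standard one-way
ANOVA.  Families of p-values are Bonferroni-corrected per output table.
Correlations with clinician-rated symptom scales are two-tailed Pearson,
computed at the participant level (the four samples averaged first, so
repeated samples are not treated as independent observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assembly import SYMPTOM_SCALES


@dataclass
class StatsConfig:
    alpha: float = 0.05
    normality_alpha: float = 0.05
    variance_alpha: float = 0.05
    correction: str = "bonferroni"


@dataclass
class GroupComparison:
    feature: str
    pair: str  # e.g. "MDD-HC"
    mean_difference_pct: float
    test_used: str  # anova | welch | mann_whitney
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False
    assumption_log: dict[str, float] = field(default_factory=dict)


@dataclass
class SymptomCorrelation:
    feature: str
    scale: str
    group: str
    r: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False


def percent_difference(
    values_a: np.ndarray, values_b: np.ndarray
) -> float:
    """100 * (mean_a - mean_b) / mean_b with b as the reference group."""
    mb = float(np.mean(values_b))
    if mb == 0:
        return float("nan")
    return 100.0 * (float(np.mean(values_a)) - mb) / mb


def welch_anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F* statistic and p-value)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], float)
    means = np.array([np.mean(g) for g in groups])
    vars_ = np.array([np.var(g, ddof=1) for g in groups])
    w = ns / vars_
    sw = w.sum()
    grand = (w * means).sum() / sw
    num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / sw) ** 2 / (ns - 1)).sum() / (k**2 - 1)
    f = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    p = float(sps.f.sf(f, k - 1, df2))
    return float(f), p


def route_and_test(
    values_by_group: dict[str, np.ndarray],
    cfg: StatsConfig | None = None,
    force_route: str | None = None,
) -> tuple[str, float, float, dict[str, float]]:
    """Pick and run the appropriate group-difference test.

    Returns (test_used, statistic, p, assumption_log).  For two groups the
    ANOVA specialization is the classical F = t^2 relation, and the
    Mann-Whitney route reports the U statistic.
    """
    cfg = cfg or StatsConfig()
    groups = [np.asarray(v, float) for v in values_by_group.values()]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise ValueError("need >= 2 groups with >= 3 values each")
    log: dict[str, float] = {}
    route = force_route
    if route is None:
        normal = True
        for name, g in zip(values_by_group, groups):
            if np.ptp(g) == 0:
                log[f"shapiro_p_{name}"] = 0.0
                normal = False
                continue
            p = float(sps.shapiro(g).pvalue)
            log[f"shapiro_p_{name}"] = p
            if p < cfg.normality_alpha:
                normal = False
        if not normal:
            route = "mann_whitney"
        else:
            lev_p = float(sps.levene(*groups).pvalue)
            log["levene_p"] = lev_p
            route = "welch" if lev_p < cfg.variance_alpha else "anova"

    if route == "anova":
        res = sps.f_oneway(*groups)
        return "anova", float(res.statistic), float(res.pvalue), log
    if route == "welch":
        f, p = welch_anova_f(groups)
        return "welch", f, p, log
    if route == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney route requires exactly 2 groups")
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return "mann_whitney", float(res.statistic), float(res.pvalue), log
    raise ValueError(f"unknown route: {route!r}")


def bonferroni(p_values: np.ndarray, alpha: float = 0.05):
    """p_adj = min(1, m*p); significant iff p_adj < alpha."""
    p = np.asarray(p_values, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, len(p) * p)
    return adj, adj < alpha


def participant_means(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Average each participant's samples into one row per participant."""
    keep = ["participant_id", "group"] + [
        c for c in features + SYMPTOM_SCALES if c in table.columns
    ]
    return (
        table[keep]
        .groupby(["participant_id", "group"], sort=True)
        .mean()
        .reset_index()
    )


def compare_groups(
    table: pd.DataFrame,
    features: list[str],
    pairs: list[tuple[str, str]] = (("MDD", "HC"), ("SSD", "HC")),
    cfg: StatsConfig | None = None,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Table of per-feature pairwise group comparisons (patient vs HC).

    The unit of analysis is the participant (sample means) unless
    ``per_sample`` is set.  The Bonferroni family is every test in the
    produced table.
    """
    cfg = cfg or StatsConfig()
    unit = table if per_sample else participant_means(table, features)
    rows: list[GroupComparison] = []
    for feat in features:
        for a, b in pairs:
            va = unit.loc[unit["group"] == a, feat].dropna().to_numpy()
            vb = unit.loc[unit["group"] == b, feat].dropna().to_numpy()
            if len(va) < 3 or len(vb) < 3:
                continue
            pct = percent_difference(va, vb)
            test, stat, p, log = route_and_test({a: va, b: vb}, cfg)
            rows.append(
                GroupComparison(feat, f"{a}-{b}", pct, test, stat, p, assumption_log=log)
            )
    if not rows:
        return pd.DataFrame(
            columns=["feature", "pair", "mean_difference_pct", "test_used",
                     "statistic", "p_raw", "p_adjusted", "significant"]
        )
    adj, sig = bonferroni(np.array([r.p_raw for r in rows]), cfg.alpha)
    for r, pa, s in zip(rows, adj, sig):
        r.p_adjusted, r.significant = float(pa), bool(s)
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "pair": r.pair,
                "mean_difference_pct": r.mean_difference_pct,
                "test_used": r.test_used,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def correlate_symptoms(
    table: pd.DataFrame,
    features: list[str],
    scales: list[str] | None = None,
    groups: tuple[str, ...] = ("MDD", "SSD"),
    cfg: StatsConfig | None = None,
) -> pd.DataFrame:
    """Two-tailed Pearson correlations feature x scale x patient group.

    Features are averaged to the participant level first; the Bonferroni
    family is all tests in the produced table.  Zero-variance scores in a
    group yield a missing cell rather than a spurious correlation.
    """
    cfg = cfg or StatsConfig()
    scales = scales or [s for s in SYMPTOM_SCALES if s in table.columns]
    unit = participant_means(table, features)
    rows: list[SymptomCorrelation] = []
    for feat in features:
        for scale in scales:
            for group in groups:
                sub = unit[unit["group"] == group][[feat, scale]].dropna()
                if len(sub) < 3:
                    continue
                x = sub[feat].to_numpy()
                y = sub[scale].to_numpy()
                if np.ptp(y) == 0 or np.ptp(x) == 0:
                    continue
                r, p = sps.pearsonr(x, y)
                rows.append(SymptomCorrelation(feat, scale, group, float(r), float(p)))
    if not rows:
        return pd.DataFrame(
            columns=["feature", "scale", "group", "r", "p_raw", "p_adjusted", "significant"]
        )
    adj, sig = bonferroni(np.array([r.p_raw for r in rows]), cfg.alpha)
    for r, pa, s in zip(rows, adj, sig):
        r.p_adjusted, r.significant = float(pa), bool(s)
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "scale": r.scale,
                "group": r.group,
                "r": r.r,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
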