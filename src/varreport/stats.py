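"""Per-condition summaries, one-way ANOVA, and Tukey-Kramer post hoc tests.

This is the analysis pipeline used to compare comprehension scores across the
seven report designs: per-design n / mean / sample SD, a one-way ANOVA across
designs, and all-pairs Tukey-Kramer comparisons computed from the summaries
(pooled within-group variance, studentized-range reference distribution,
unequal-n standard errors).  Because the Tukey machinery needs only (n, mean,
SD) per group, it can also be run directly on published summary tables.

Conventions: SDs are sample SDs (n-1 denominator); p-values are reported raw
and two-sided; significance flags are applied by the caller at their alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats as sps

from .quiz import LIKERT_IDS, ResponseSheet, ScoreRecord

#: canonical order of the seven design conditions
CONDITION_ORDER = (
    "table",
    "bar",
    "bubble",
    "treemap",
    "heatmap",
    "zoom_treemap",
    "zoom_partition",
)


class StatsError(Exception):
    pass


class DegenerateError(StatsError):
    """Zero within-group variance where a finite test statistic is required."""


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyResult:
    pair: tuple[str, str]
    diff: float
    se: float
    q: float
    p_adj: float


def _condition_sort_key(condition: str) -> tuple[int, str]:
    try:
        return (CONDITION_ORDER.index(condition), condition)
    except ValueError:
        return (len(CONDITION_ORDER), condition)


def summarize(scores: list[ScoreRecord]) -> list[ConditionSummary]:
    """Per-condition n, mean, and sample SD, in canonical design order."""
    by_condition: dict[str, list[float]] = {}
    for rec in scores:
        by_condition.setdefault(rec.condition, []).append(rec.score)
    out = []
    for cond in sorted(by_condition, key=_condition_sort_key):
        vals = np.asarray(by_condition[cond], dtype=float)
        if vals.size < 2:
            raise StatsError(f"condition {cond!r} has fewer than 2 records")
        out.append(
            ConditionSummary(
                condition=cond,
                n=int(vals.size),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)),
            )
        )
    return out


def anova_oneway(groups: list[list[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the between/within decomposition."""
    if len(groups) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("every group needs at least 2 observations")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_between, df_within=df_within, p=1.0)
        raise DegenerateError("zero within-group variance with unequal means: infinite F")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)


def studentized_range_cdf(q: float, k: int, df: int) -> float:
    """P(Q <= q) for the studentized range of k group means with df error df.

    Backed by scipy's numerically integrated implementation (outer integral
    over the pooled-scale distribution, inner over the location of the range),
    accurate to well within 1e-6 on the ranges used here.
    """
    if q < 0:
        raise StatsError("q must be non-negative")
    if k < 2 or df < 1:
        raise StatsError("need k >= 2 groups and df >= 1")
    if q == 0.0:
        return 0.0
    return float(np.clip(sps.studentized_range.cdf(q, k, df), 0.0, 1.0))


def tukey_kramer(summaries: list[ConditionSummary]) -> list[TukeyResult]:
    """All-pairs Tukey-Kramer comparisons from per-group summary statistics.

    Pooled MSE = sum (n_i - 1) s_i^2 / sum (n_i - 1); for each pair,
    SE = sqrt(MSE/2 * (1/n_i + 1/n_j)) (the Kramer unequal-n form),
    q = |mean_i - mean_j| / SE, and p_adj = 1 - F_Q(q; k, df) with
    df = sum (n_i - 1).
    """
    k = len(summaries)
    if k < 2:
        raise StatsError("Tukey-Kramer needs at least 2 groups")
    df = sum(s.n - 1 for s in summaries)
    if df < 1:
        raise StatsError("not enough observations to pool a variance")
    mse = sum((s.n - 1) * s.sd**2 for s in summaries) / df
    if mse == 0.0:
        raise DegenerateError("pooled within-group variance is zero")
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = summaries[i], summaries[j]
            diff = a.mean - b.mean
            se = float(np.sqrt(mse / 2.0 * (1.0 / a.n + 1.0 / b.n)))
            q = abs(diff) / se
            p_adj = 1.0 - studentized_range_cdf(q, k, df)
            results.append(
                TukeyResult(
                    pair=(a.condition, b.condition),
                    diff=float(diff),
                    se=se,
                    q=float(q),
                    p_adj=float(p_adj),
                )
            )
    return results


def likert_summary(
    sheets: list[ResponseSheet], item: str
) -> tuple[int, float, float]:
    """(n, mean, sample SD) of one 1-5 Likert item, blanks excluded."""
    if item not in LIKERT_IDS:
        raise StatsError(f"unknown Likert item {item!r}")
    vals = np.asarray(
        [s.likert[item] for s in sheets if s.likert.get(item) is not None],
        dtype=float,
    )
    if vals.size == 0:
        raise StatsError(f"no responses for {item}")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return int(vals.size), float(vals.mean()), sd


def analyze(
    scores: list[ScoreRecord],
    sheets: list[ResponseSheet] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Full pipeline: summaries, ANOVA, Tukey table, and Likert table as JSON-able dict."""
    summaries = summarize(scores)
    groups: dict[str, list[float]] = {}
    for rec in scores:
        groups.setdefault(rec.condition, []).append(rec.score)
    anova = anova_oneway([groups[s.condition] for s in summaries])
    tukey = tukey_kramer(summaries)
    doc = {
        "summaries": [
            {"condition": s.condition, "n": s.n, "mean": s.mean, "sd": s.sd}
            for s in summaries
        ],
        "anova": {
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p": anova.p,
        },
        "tukey": [
            {
                "pair": list(t.pair),
                "diff": t.diff,
                "se": t.se,
                "q": t.q,
                "p_adj": t.p_adj,
                "significant": bool(t.p_adj < alpha),
            }
            for t in tukey
        ],
        "alpha": alpha,
    }
    if sheets is not None:
        likert = {}
        for item in LIKERT_IDS:
            try:
                n, mean, sd = likert_summary(sheets, item)
            except StatsError:
                continue
            likert[item] = {"n": n, "mean": mean, "sd": sd}
        doc["likert"] = likert
    return doc


def load_study_summaries() -> list[ConditionSummary]:
    """The packaged published per-design comprehension summary statistics."""
    text = (
        resources.files("varreport.data").joinpath("study_summary.json").read_text()
    )
    doc = json.loads(text)
    return [
        ConditionSummary(
            condition=row["condition"], n=row["n"], mean=row["mean"], sd=row["sd"]
        )
        for row in doc["comprehension"]
    ]
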