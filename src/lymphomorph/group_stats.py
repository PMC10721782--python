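"""Group-level statistics: mean ± SD, t-tests, one-way ANOVA, star flags.

Thin, explicit layer over scipy.stats / statsmodels so every comparison in
the pipeline carries the same conventions: sample SD (n−1), two-sided Welch
t-test by default, omnibus one-way ANOVA for k > 2 groups, and the usual
significance stars at strict 0.05 / 0.01 / 0.001 cutoffs. Reported p values
are uncorrected unless Holm correction is explicitly requested.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclasses.dataclass
class MeanSD:
    mean: float
    sd: float  # NaN marks "undefined" for n == 1
    n: int


@dataclasses.dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


@dataclasses.dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclasses.dataclass
class GroupComparison:
    """Summary of a two- or k-group comparison as reported in figures."""

    labels: list[str]
    means: list[float]
    sds: list[float]
    ns: list[int]
    test: str
    statistic: float
    p: float
    stars: str


def mean_sd(values) -> MeanSD:
    """Mean and sample SD (n−1 denominator); SD is NaN for a single value."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("empty input")
    sd = float(v.std(ddof=1)) if v.size > 1 else math.nan
    return MeanSD(mean=float(v.mean()), sd=sd, n=int(v.size))


def t_test(a, b, variant: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test (Welch by default, pooled optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise StatsError("degenerate: both variances zero and means equal")
        return TTestResult(t=math.inf, df=a.size + b.size - 2, p=0.0, variant=variant)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue), variant=variant
    )


def one_way_anova(groups) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA, F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise StatsError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise StatsError("degenerate: all values identical")
    f, p = sps.f_oneway(*groups)
    n_total = int(pooled.size)
    return AnovaResult(
        f=float(f),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        p=float(p),
    )


def star_flags(p: float) -> str:
    """Significance stars at strict thresholds: *<0.05, **<0.01, ***<0.001."""
    if not (0.0 <= p <= 1.0):
        raise StatsError(f"p value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def holm_correct(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (off by default in all reports)."""
    _, adjusted, _, _ = multipletests(np.asarray(p_values, float), method="holm")
    return adjusted


def compare_groups(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    test: str = "auto",
    t_variant: str = "welch",
) -> GroupComparison:
    """Summarize and test named groups; t-test for 2 groups, ANOVA for more."""
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in labels]
    if test == "auto":
        test = "ttest" if len(groups) == 2 else "anova"
    summaries = [mean_sd(g) for g in groups]
    if test == "ttest":
        if len(groups) != 2:
            raise StatsError("t-test requires exactly 2 groups")
        res = t_test(groups[0], groups[1], variant=t_variant)
        statistic, p, name = res.t, res.p, f"t ({res.variant})"
    elif test == "anova":
        res = one_way_anova(groups)
        statistic, p, name = res.f, res.p, "one-way ANOVA"
    else:
        raise StatsError(f"unknown test {test!r}")
    return GroupComparison(
        labels=labels,
        means=[s.mean for s in summaries],
        sds=[s.sd for s in summaries],
        ns=[s.n for s in summaries],
        test=name,
        statistic=statistic,
        p=p,
        stars=star_flags(p),
    )
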