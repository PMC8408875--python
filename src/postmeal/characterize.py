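"""Descriptive analytics of the postprandial inflammatory response.

Covers the marker transforms (ln(IL-6 + 1)), responder summaries and
percent rises, cross-sectional coefficients of variation, Levene's test
of variance heterogeneity between time points, feature-marker Pearson
correlation tables, and the repeated-measures sex/age interaction test.

Percent values carry two reporting conventions used side by side in the
source literature: one-decimal percentages are truncated (42.74 -> 42.7)
and integer percentages are rounded (168.75 -> 169); see
:func:`format_percent`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "ln_plus_one",
    "percent_change",
    "format_percent",
    "responder_summary",
    "cross_sectional_cv",
    "levene_test",
    "correlation_matrix",
    "rm_interaction_test",
    "ResponderSummary",
    "DispersionSummary",
    "VarianceHeterogeneityTest",
]


def ln_plus_one(value):
    """Natural log of (value + 1); the variance-stabilizing IL-6 transform."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("ln(x + 1) requires x >= 0")
    out = np.log1p(arr)
    return float(out) if np.isscalar(value) else out


def percent_change(baseline: float, followup: float) -> float:
    """100 * (followup - baseline) / baseline."""
    if baseline <= 0:
        raise InvalidParameterError("percent change needs a positive baseline")
    return 100.0 * (followup - baseline) / baseline


def format_percent(value: float, decimals: int = 0) -> float:
    """Render a percentage per the reporting convention.

    decimals == 0 rounds to the nearest integer; decimals >= 1 truncates
    toward zero at that many decimals (e.g. 42.74 -> 42.7 at one decimal).
    """
    if decimals == 0:
        return float(round(value))
    factor = 10.0**decimals
    return math.trunc(value * factor) / factor


@dataclass(frozen=True)
class ResponderSummary:
    """Riser-fraction summary of a marker's 6-h change from fasting."""

    n_total: int
    n_rising: int
    fraction_rising: float
    mean_rise: float
    pct_rise: float
    responder_mean_fasting: float | None
    responder_mean_6h: float | None
    responder_mean_rise: float | None
    responder_pct_rise: float | None


@dataclass(frozen=True)
class DispersionSummary:
    mean: float
    sd: float
    cv_pct: float


@dataclass(frozen=True)
class VarianceHeterogeneityTest:
    statistic: float
    df1: int
    df2: int
    p_value: float


def responder_summary(
    value_0h: np.ndarray, value_6h: np.ndarray, epsilon: float = 0.0
) -> ResponderSummary:
    """Summarize the rising participants for one marker.

    A participant is "rising" when (6 h - fasting) > epsilon (strict by
    default).  Cohort and responder-only percent rises are computed from
    the relevant group means.
    """
    v0 = np.asarray(value_0h, dtype=float)
    v6 = np.asarray(value_6h, dtype=float)
    ok = ~(np.isnan(v0) | np.isnan(v6))
    v0, v6 = v0[ok], v6[ok]
    if v0.size == 0:
        raise InsufficientDataError("no participants with both 0-h and 6-h values")
    rise = v6 - v0
    rising = rise > epsilon
    n_rising = int(rising.sum())
    if n_rising:
        rm0 = float(v0[rising].mean())
        rm6 = float(v6[rising].mean())
        resp = dict(
            responder_mean_fasting=rm0,
            responder_mean_6h=rm6,
            responder_mean_rise=rm6 - rm0,
            responder_pct_rise=percent_change(rm0, rm6),
        )
    else:
        resp = dict(
            responder_mean_fasting=None,
            responder_mean_6h=None,
            responder_mean_rise=None,
            responder_pct_rise=None,
        )
    return ResponderSummary(
        n_total=int(v0.size),
        n_rising=n_rising,
        fraction_rising=n_rising / v0.size,
        mean_rise=float(rise.mean()),
        pct_rise=percent_change(float(v0.mean()), float(v6.mean())),
        **resp,
    )


def cross_sectional_cv(values: np.ndarray) -> DispersionSummary:
    """Between-participant coefficient of variation at one time point.

    CV% = 100 * sample SD (n-1 denominator) / mean; requires a positive
    mean and n >= 2.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    mean = float(v.mean())
    if mean <= 0:
        raise InvalidParameterError("CV undefined for non-positive mean")
    sd = float(v.std(ddof=1))
    return DispersionSummary(mean=mean, sd=sd, cv_pct=100.0 * sd / mean)


def levene_test(*groups, center: str = "mean") -> VarianceHeterogeneityTest:
    """Levene's test of variance heterogeneity across groups.

    center='mean' is the classic Levene statistic (an ANOVA on absolute
    deviations from the group mean); center='median' gives the
    Brown-Forsythe variant.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    clean = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in clean):
        raise InsufficientDataError("each group needs n >= 2")
    w, p = stats.levene(*clean, center=center)
    k = len(clean)
    n_total = sum(g.size for g in clean)
    return VarianceHeterogeneityTest(
        statistic=float(w), df1=k - 1, df2=n_total - k, p_value=float(p)
    )


def correlation_matrix(
    features: pd.DataFrame,
    markers: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of features with marker columns.

    Both inputs are indexed by participant.  Returns a tidy table with one
    row per (feature, marker column) pair: r, the two-sided p-value from
    the t distribution, and a significance flag at ``alpha``.  Pairs with
    fewer than three complete observations raise.
    """
    joined = features.join(markers, how="inner")
    rows = []
    for f in features.columns:
        for m in markers.columns:
            sub = joined[[f, m]].dropna()
            if len(sub) < 3:
                raise InsufficientDataError(
                    f"correlation ({f}, {m}) needs >= 3 complete pairs"
                )
            r, p = stats.pearsonr(sub[f], sub[m])
            rows.append(
                {
                    "feature": f,
                    "marker": m,
                    "n": len(sub),
                    "r": float(r),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def rm_interaction_test(
    long: pd.DataFrame,
    dv: str = "value",
    within: str = "time_h",
    subject: str = "participant_id",
    between: str = "group",
) -> dict:
    """Mixed repeated-measures ANOVA; returns the time-by-group interaction.

    ``long`` holds one row per participant x time point with the marker
    value in ``dv`` and a two-or-more-level between factor (e.g. sex, or
    age dichotomized at the cohort median).  Participants missing any time
    point are dropped (their count is reported).
    """
    import pingouin as pg

    n_times = long[within].nunique()
    counts = long.groupby(subject)[within].nunique()
    complete = counts[counts == n_times].index
    n_dropped = int((counts != n_times).sum())
    data = long[long[subject].isin(complete)]
    if data[between].nunique() < 2:
        raise InsufficientDataError("between factor needs >= 2 levels")
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, subject=subject, between=between
    )
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    return {
        "F": float(inter["F"]),
        "df1": float(inter["DF1"]),
        "df2": float(inter["DF2"]),
        "p_value": float(inter["p_unc"] if "p_unc" in inter else inter["p-unc"]),
        "n_dropped": n_dropped,
        "table": aov,
    }
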