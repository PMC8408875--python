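"""Feature ranking and discrimination for postprandial inflammation.

Random-forest regression with cross-validated predictive ability
(Q^2 = 1 - PRESS/TSS), multivariable OLS with variance-inflation-factor
screening, percentile dichotomization of the outcome, and ROC analysis
with a DeLong 95% confidence interval for the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .exceptions import EstimationError, InsufficientDataError, InvalidParameterError

__all__ = [
    "RFReport",
    "LinearModelFit",
    "ROCReport",
    "rf_rank",
    "vif",
    "multivariable_fit",
    "dichotomize_at_percentile",
    "roc_auc",
]


@dataclass
class RFReport:
    target: str
    features: list[str]  # ranked, most important first
    importances: np.ndarray  # aligned with `features`, sums to 1
    r2: float  # in-sample fit on the full data
    q2: float  # 1 - PRESS/TSS over k-fold CV
    n_trees: int
    n_folds: int
    seed: int
    n_used: int
    n_dropped: int


def rf_rank(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> RFReport:
    """Rank features by random-forest importance; report R^2 and Q^2.

    The forest uses p/3 features per split (regression default).  Q^2 is
    computed from k-fold cross-validation as 1 - PRESS/TSS, with PRESS the
    sum of held-out squared errors and TSS taken about each training
    fold's mean (so the reference prediction never sees held-out data).
    Rows with any missing value are dropped and counted.
    """
    x = pd.DataFrame(features)
    y = pd.Series(np.asarray(target, dtype=float), index=x.index)
    ok = x.notna().all(axis=1) & y.notna()
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 10 * n_folds:
        raise InsufficientDataError(f"need n >= {10 * n_folds}, have {n}")
    if np.ptp(y.to_numpy()) == 0:
        raise EstimationError("target is constant; nothing to predict")

    def make_forest(s):
        return RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1.0 / 3.0,
            random_state=s,
            n_jobs=1,
        )

    full = make_forest(seed).fit(x, y)
    r2 = float(full.score(x, y))

    press = 0.0
    tss = 0.0
    y_arr = y.to_numpy()
    for fold, (tr, te) in enumerate(
        KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(x)
    ):
        model = make_forest(seed + fold + 1).fit(x.iloc[tr], y_arr[tr])
        pred = model.predict(x.iloc[te])
        press += float(np.sum((y_arr[te] - pred) ** 2))
        tss += float(np.sum((y_arr[te] - y_arr[tr].mean()) ** 2))
    q2 = 1.0 - press / tss

    imp = full.feature_importances_
    order = np.argsort(imp)[::-1]
    return RFReport(
        target=getattr(target, "name", None) or "target",
        features=[x.columns[i] for i in order],
        importances=imp[order] / imp.sum(),
        r2=r2,
        q2=q2,
        n_trees=n_trees,
        n_folds=n_folds,
        seed=seed,
        n_used=n,
        n_dropped=n_dropped,
    )


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature (1 / (1 - R^2_k)).

    Each feature is regressed (with intercept) on all the others; exact
    collinearity yields ``inf`` for the features involved.  VIF > 10 is
    the conventional "high" flag.
    """
    x = pd.DataFrame(features).astype(float)
    if len(x) <= x.shape[1] + 1:
        raise InsufficientDataError("need n > number of features + 1")
    out = {}
    cols = list(x.columns)
    for k, col in enumerate(cols):
        others = x[[c for c in cols if c != col]].to_numpy()
        design = np.column_stack([np.ones(len(x)), others])
        y = x[col].to_numpy()
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ssr = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ssr / sst
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class LinearModelFit:
    outcome: str
    params: pd.DataFrame  # coef, std_beta, se, p, vif per predictor
    r2: float
    n: int


def multivariable_fit(
    outcome: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
) -> LinearModelFit:
    """Multivariable OLS with standardized betas and per-predictor VIF."""
    import statsmodels.api as sm

    x = pd.DataFrame(predictors).astype(float)
    y = pd.Series(np.asarray(outcome, dtype=float), index=x.index)
    if len(x) <= x.shape[1] + 1:
        raise InsufficientDataError("need n > number of predictors + 1")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        corr = x.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise EstimationError(f"singular design; near-collinear predictors: {worst}")
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    std_beta = {c: fit.params[c] * x[c].std(ddof=1) / sd_y for c in x.columns}
    vifs = vif(x) if x.shape[1] > 1 else pd.Series({x.columns[0]: 1.0})
    params = pd.DataFrame(
        {
            "coef": fit.params[x.columns],
            "std_beta": pd.Series(std_beta),
            "se": fit.bse[x.columns],
            "p": fit.pvalues[x.columns],
            "vif": vifs,
        }
    )
    return LinearModelFit(
        outcome=getattr(outcome, "name", None) or "outcome",
        params=params,
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


def dichotomize_at_percentile(
    values: np.ndarray, pct: float
) -> tuple[np.ndarray, float]:
    """Binary labels: 1 iff value > the pct-th empirical percentile.

    The cutoff is the linear-interpolation quantile; it is returned with
    the labels.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need n >= 2")
    if not 0 <= pct <= 100:
        raise InvalidParameterError("pct must be in [0, 100]")
    cutoff = float(np.percentile(v, pct))
    return (v > cutoff).astype(int), cutoff


@dataclass
class ROCReport:
    score: str
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong (1988) variance of the empirical AUC via placement values."""
    m, n = pos.size, neg.size
    # V10[i]: fraction of negatives below pos[i] (ties count half)
    v10 = np.array(
        [(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos]
    )
    v01 = np.array(
        [(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg]
    )
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: np.ndarray, labels: np.ndarray, score_name: str = "score") -> ROCReport:
    """Empirical ROC AUC via the Mann-Whitney identity, with DeLong 95% CI.

    AUC = (concordant pairs + half the tied pairs) / (n_pos * n_neg).  The
    confidence interval is clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise InvalidParameterError("both outcome classes must be present")
    # Mann-Whitney U through midranks handles ties exactly
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    var = _delong_variance(pos, neg, auc)
    half = 1.959963984540054 * np.sqrt(var)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    return ROCReport(
        score=score_name,
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        fpr=fpr,
        tpr=tpr,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )
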