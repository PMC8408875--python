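"""Manifest-variable path analysis by maximum likelihood.

A directed acyclic linear system on observed variables is fit by
minimizing the ML discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

between the model-implied covariance Sigma(theta) = (I-B)^-1 Psi (I-B)^-T
and the sample covariance S.  Free parameters are the edge coefficients
(B), residual variances of endogenous variables, and the full covariance
block of the exogenous variables.  chi^2 = (n-1) F at the optimum;
standard errors come from the inverse numerical Hessian of F scaled by
2/(n-1).  CFI/TLI are computed against the independence baseline (all
covariances zero, variances free); RMSEA from the noncentrality estimate
max(chi^2 - df, 0).

Optimization is deterministic: quasi-Newton (BFGS) from a fixed start
(zero coefficients, sample variances, sample exogenous covariances), with
variances kept positive through a log/Cholesky parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import EstimationError, InsufficientDataError, InvalidParameterError

__all__ = ["PathSpec", "PathFit", "fit_path_model", "fit_indices", "select_sem_inputs"]


@dataclass(frozen=True)
class PathSpec:
    """Nodes and directed edges of a manifest-variable path model."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # (source, target)

    def __post_init__(self):
        for s, t in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise InvalidParameterError(f"edge ({s}, {t}) uses an undeclared node")
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[str]:
        indeg = {v: 0 for v in self.nodes}
        for _, t in self.edges:
            indeg[t] += 1
        queue = [v for v in self.nodes if indeg[v] == 0]
        order = []
        while queue:
            v = queue.pop()
            order.append(v)
            for s, t in self.edges:
                if s == v:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        queue.append(t)
        if len(order) != len(self.nodes):
            raise InvalidParameterError("path specification contains a cycle")
        return order

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.edges}
        return tuple(v for v in self.nodes if v not in targets)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.edges}
        return tuple(v for v in self.nodes if v in targets)

    @property
    def n_free(self) -> int:
        q = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + q * (q + 1) // 2


@dataclass
class PathFit:
    """Estimates and fit panel for a fitted path model."""

    estimates: pd.DataFrame  # per edge: estimate, std_beta, se, p
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float | None
    tli_raw: float | None
    rmsea: float | None
    n: int
    implied_cov: pd.DataFrame
    converged: bool


def _unpack(theta, spec: PathSpec, idx, n_exo):
    p = len(spec.nodes)
    b = np.zeros((p, p))
    k = 0
    for s, t in spec.edges:
        b[idx[t], idx[s]] = theta[k]
        k += 1
    psi = np.zeros((p, p))
    for v in spec.endogenous:
        psi[idx[v], idx[v]] = np.exp(theta[k])
        k += 1
    # exogenous block via Cholesky with log-diagonal
    lmat = np.zeros((n_exo, n_exo))
    for i in range(n_exo):
        for j in range(i + 1):
            if i == j:
                lmat[i, i] = np.exp(theta[k])
            else:
                lmat[i, j] = theta[k]
            k += 1
    exo_idx = [idx[v] for v in spec.exogenous]
    psi[np.ix_(exo_idx, exo_idx)] = lmat @ lmat.T
    return b, psi


def _implied_cov(theta, spec, idx, n_exo):
    b, psi = _unpack(theta, spec, idx, n_exo)
    p = len(spec.nodes)
    inv = np.linalg.inv(np.eye(p) - b)
    return inv @ psi @ inv.T


def _discrepancy(sigma, s_mat, logdet_s):
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        tr = float(np.trace(np.linalg.solve(sigma, s_mat)))
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + tr - logdet_s - s_mat.shape[0]


def fit_path_model(data: pd.DataFrame, spec: PathSpec, tol: float = 1e-10) -> PathFit:
    """Fit a path model to complete-case data by maximum likelihood.

    Returns per-edge unstandardized estimates, standardized betas
    (estimate * sd(source)/sd(target), sample SDs), SEs and normal-theory
    p-values, plus the chi^2/CFI/TLI/RMSEA panel.
    """
    cols = list(spec.nodes)
    frame = data[cols].dropna()
    n = len(frame)
    if n < 5 * spec.n_free:
        raise InsufficientDataError(
            f"need >= {5 * spec.n_free} complete rows for {spec.n_free} free parameters"
        )
    s_mat = np.cov(frame.to_numpy(), rowvar=False, ddof=1)
    sign, logdet_s = np.linalg.slogdet(s_mat)
    if sign <= 0:
        raise EstimationError("sample covariance is singular")
    idx = {v: i for i, v in enumerate(cols)}
    n_exo = len(spec.exogenous)

    # deterministic start: zero coefficients, sample variances,
    # sample exogenous covariance block
    theta0 = []
    theta0 += [0.0] * len(spec.edges)
    theta0 += [np.log(s_mat[idx[v], idx[v]]) for v in spec.endogenous]
    exo_idx = [idx[v] for v in spec.exogenous]
    chol = np.linalg.cholesky(s_mat[np.ix_(exo_idx, exo_idx)])
    for i in range(n_exo):
        for j in range(i + 1):
            theta0.append(np.log(chol[i, i]) if i == j else chol[i, j])
    theta0 = np.asarray(theta0)

    def objective(theta):
        return _discrepancy(_implied_cov(theta, spec, idx, n_exo), s_mat, logdet_s)

    res = optimize.minimize(
        objective, theta0, method="BFGS", options={"gtol": tol, "maxiter": 2000}
    )
    # polish with Nelder-Mead if the quasi-Newton stalled
    if not res.success and res.fun > 1e-8:
        res = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
    theta = res.x
    f_min = float(objective(theta))
    if not np.isfinite(f_min):
        raise EstimationError("path model optimization did not converge")

    chi2 = max((n - 1) * f_min, 0.0)
    p = len(cols)
    df = p * (p + 1) // 2 - spec.n_free

    # numerical Hessian of F -> asymptotic covariance 2/(n-1) H^-1
    se = np.full(len(spec.edges), np.nan)
    hess = _numerical_hessian(objective, theta)
    try:
        acov = 2.0 / (n - 1) * np.linalg.inv(hess)
        diag = np.diag(acov)[: len(spec.edges)]
        se = np.sqrt(np.maximum(diag, 0.0))
    except np.linalg.LinAlgError:
        pass

    sds = frame.std(ddof=1)
    rows = []
    for k, (s, t) in enumerate(spec.edges):
        est = theta[k]
        z = est / se[k] if se[k] > 0 else np.nan
        rows.append(
            {
                "source": s,
                "target": t,
                "estimate": est,
                "std_beta": est * sds[s] / sds[t],
                "se": se[k],
                "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )

    # independence baseline: diagonal Sigma with free variances
    f_base = float(np.sum(np.log(np.diag(s_mat))) - logdet_s)
    chi2_b = max((n - 1) * f_base, 0.0)
    df_b = p * (p - 1) // 2
    cfi, tli, tli_raw, rmsea = fit_indices(chi2, df, chi2_b, df_b, n)

    sigma = _implied_cov(theta, spec, idx, n_exo)
    return PathFit(
        estimates=pd.DataFrame(rows),
        chi2=chi2,
        df=df,
        baseline_chi2=chi2_b,
        baseline_df=df_b,
        cfi=cfi,
        tli=tli,
        tli_raw=tli_raw,
        rmsea=rmsea,
        n=n,
        implied_cov=pd.DataFrame(sigma, index=cols, columns=cols),
        converged=bool(np.isfinite(f_min)),
    )


def _numerical_hessian(fun, x, eps: float = 1e-5) -> np.ndarray:
    k = x.size
    h = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i + 1):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            if i == j:
                val = (fun(x + ei) - 2 * f0 + fun(x - ei)) / eps**2
            else:
                val = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * eps**2)
            h[i, j] = h[j, i] = val
    return h


def fit_indices(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int, n: int
) -> tuple[float, float | None, float | None, float | None]:
    """CFI, TLI (capped at 1 with the raw value retained) and RMSEA.

    cfi = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    tli = ((chi2_b/df_b) - (chi2_m/df_m)) / ((chi2_b/df_b) - 1);
    rmsea = sqrt(max(chi2_m - df_m, 0) / (df_m (n - 1))).
    TLI and RMSEA are None when df_m = 0 (saturated model).
    """
    if df_b < df_m or df_m < 0:
        raise InvalidParameterError("need df_b >= df_m >= 0")
    if n < 2:
        raise InvalidParameterError("need n >= 2")
    num = max(chi2_m - df_m, 0.0)
    denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    if df_m == 0:
        return cfi, None, None, None
    ratio_b = chi2_b / df_b
    if ratio_b == 1.0:  # degenerate baseline: TLI denominator vanishes
        tli_raw = tli = None
    else:
        tli_raw = (ratio_b - chi2_m / df_m) / (ratio_b - 1.0)
        tli = min(tli_raw, 1.0)
    rmsea = float(np.sqrt(num / (df_m * (n - 1))))
    return cfi, tli, tli_raw, rmsea


def select_sem_inputs(
    features: pd.DataFrame,
    target,
    k: int = 6,
    exclude_postprandial: bool = False,
    seed: int = 0,
) -> list[str]:
    """Top-k covariates by random-forest importance for path-model inclusion.

    With ``exclude_postprandial`` the postprandial glycemia/lipemia curve
    features (iAUCs, rises, maxima, timed concentrations) are removed from
    the returned list, keeping only fasting and non-meal covariates.
    """
    from .predict import rf_rank

    if k == 0:
        return []
    report = rf_rank(features, target, seed=seed)
    postprandial = {
        "glu_1h_iauc", "glu_2h_iauc", "glu_30min_rise", "glu_1h_rise",
        "glu_max1", "glu_max2", "tg_6h_iauc", "tg_6h_rise", "tg_max",
        "tg_at_4h", "tg_at_6h",
    }
    ranked = report.features
    if exclude_postprandial:
        ranked = [f for f in ranked if f not in postprandial]
    return ranked[:k]
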