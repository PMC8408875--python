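"""Two-sample Mendelian-randomization estimators and diagnostics.

All methods operate on harmonized summary statistics: per SNP j an
allele-aligned exposure association (beta_exp = gamma_hat_j with SE
se_exp) and outcome association (beta_out = Gamma_hat_j with SE se_out).
Implemented from first principles:

* Wald ratio (single SNP) with first-order SE;
* inverse-variance weighted (IVW) estimate, fixed or multiplicative
  random effects, equivalent to weighted regression through the origin;
* MR-Egger weighted regression with a free intercept (the intercept is
  the directional-pleiotropy test);
* Cochran's Q (IVW) and Ruecker's Q' (Egger) heterogeneity statistics;
* MR-PRESSO: simulation-based global residual-sum-of-squares test,
  per-SNP outlier detection with Bonferroni correction, and a
  distortion test;
* MR-RAPS: robust adjusted profile score with optional overdispersion
  (tau^2) and optional Huber loss (k = 1.345), sandwich SEs;
* leave-one-out IVW influence analysis;
* per-SNP instrument-strength F statistics ((beta/se)^2; > 20 strong).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import EstimationError, InsufficientDataError, InvalidParameterError

__all__ = [
    "MREstimate",
    "EggerResult",
    "HeterogeneityReport",
    "PRESSOReport",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "cochran_q",
    "mr_presso",
    "mr_raps",
    "leave_one_out",
    "instrument_strength",
]

logger = logging.getLogger(__name__)

HARMONIZED_COLUMNS = ["snp", "beta_exp", "se_exp", "beta_out", "se_out"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_HUBER_K = 1.345


@dataclass
class MREstimate:
    """A causal-effect estimate (per SD of exposure) from one MR method."""

    method: str
    beta: float
    se: float
    p: float
    n_snp: int
    model: str = "fixed"

    @property
    def ci(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return self.beta - half, self.beta + half


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass
class HeterogeneityReport:
    method: str
    statistic: float  # Cochran Q (IVW) or Ruecker Q' (Egger)
    df: int
    p: float


@dataclass
class PRESSOReport:
    rss_obs: float
    global_p: float
    outlier_p: pd.Series  # Bonferroni-adjusted per-SNP p-values
    outliers: list[str]
    distortion_p: float | None
    beta_all: float
    beta_no_outliers: float | None
    n_sim: int
    seed: int


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Allele-align exposure and outcome associations on shared SNPs.

    When the outcome's effect/other alleles are swapped relative to the
    exposure, the outcome beta is sign-flipped (and its EAF reflected).
    Strand-ambiguous palindromic SNPs (A/T, C/G) whose EAF falls in
    ``palindromic_eaf_window`` are dropped, as are SNPs whose allele
    pairs neither match nor swap.  Returns a table with columns
    snp, beta_exp, se_exp, beta_out, se_out, eaf_exp, palindromic.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    if merged.empty:
        raise InsufficientDataError("no shared SNPs between exposure and outcome")
    rows = []
    lo, hi = palindromic_eaf_window
    for rec in merged.itertuples():
        e1, e2 = rec.effect_allele_exp, rec.other_allele_exp
        o1, o2 = rec.effect_allele_out, rec.other_allele_out
        pal = _is_palindromic(e1, e2)
        if pal and lo <= rec.eaf_exp <= hi:
            logger.info("dropping palindromic SNP %s (eaf %.2f)", rec.snp, rec.eaf_exp)
            continue
        if (o1, o2) == (e1, e2):
            beta_out = rec.beta_out
        elif (o1, o2) == (e2, e1):
            beta_out = -rec.beta_out
            logger.info("flipped outcome allele orientation for %s", rec.snp)
        else:
            logger.warning("incompatible alleles for %s; dropped", rec.snp)
            continue
        rows.append(
            {
                "snp": rec.snp,
                "beta_exp": rec.beta_exp,
                "se_exp": rec.se_exp,
                "beta_out": beta_out,
                "se_out": rec.se_out,
                "eaf_exp": rec.eaf_exp,
                "palindromic": pal,
            }
        )
    if not rows:
        raise InsufficientDataError("harmonization left no usable SNPs")
    return pd.DataFrame(rows)


def _arrays(hs: pd.DataFrame):
    return (
        hs["beta_exp"].to_numpy(float),
        hs["se_exp"].to_numpy(float),
        hs["beta_out"].to_numpy(float),
        hs["se_out"].to_numpy(float),
    )


def wald_ratio(h, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate: Gamma_hat / gamma_hat.

    The default SE is first-order (se_out / |beta_exp|); ``second_order``
    adds the exposure-uncertainty term of the delta expansion,
    sqrt(se_out^2 / beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4).
    """
    if isinstance(h, pd.DataFrame):
        if len(h) != 1:
            raise InvalidParameterError("wald_ratio takes exactly one instrument")
        h = h.iloc[0]
    if h["beta_exp"] == 0:
        raise EstimationError("beta_exp = 0: instrument carries no exposure signal")
    beta = h["beta_out"] / h["beta_exp"]
    if second_order:
        se = np.sqrt(
            h["se_out"] ** 2 / h["beta_exp"] ** 2
            + h["beta_out"] ** 2 * h["se_exp"] ** 2 / h["beta_exp"] ** 4
        )
    else:
        se = h["se_out"] / abs(h["beta_exp"])
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MREstimate("wald_ratio", float(beta), float(se), float(p), 1)


def ivw(hs: pd.DataFrame, model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted estimate across instruments.

    beta = sum(w_j b_j) / sum(w_j) with per-SNP Wald ratios b_j and
    weights w_j = gamma_hat_j^2 / se_out_j^2 — identical to weighted
    regression of the outcome betas on the exposure betas through the
    origin.  ``model='random'`` inflates the fixed-effect SE by
    max(1, sqrt(Q / (J - 1))) (multiplicative random effects).
    """
    if model not in ("fixed", "random"):
        raise InvalidParameterError(f"unknown model {model!r}")
    if len(hs) == 1:
        est = wald_ratio(hs)
        return MREstimate("ivw", est.beta, est.se, est.p, 1, model)
    bx, _, by, sy = _arrays(hs)
    w = bx**2 / sy**2
    if np.all(w == 0):
        raise EstimationError("all IVW weights are zero")
    ratios = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if model == "random":
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (len(hs) - 1)))
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MREstimate("ivw", beta, se, float(p), len(hs), model)


def mr_egger(hs: pd.DataFrame, fit_intercept: bool = True) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Instruments are first oriented so every exposure beta is non-negative
    (sign-flipping both betas leaves the causal estimate unchanged).  The
    slope is the pleiotropy-adjusted causal estimate; the intercept
    estimates average directional pleiotropy, and its p-value is the
    pleiotropy test.  SEs use the multiplicative random-effects scaling
    max(1, sqrt(Q'/(J-2))).
    """
    j = len(hs)
    if j < 3:
        raise InsufficientDataError("MR-Egger needs >= 3 instruments")
    bx, _, by, sy = _arrays(hs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    if not fit_intercept:
        # regression through the origin: identical to fixed-effect IVW
        est = ivw(hs, model="fixed")
        return EggerResult(
            MREstimate("mr_egger", est.beta, est.se, est.p, j, "fixed"), 0.0, 0.0, 1.0
        )
    x_mat = np.column_stack([np.ones(j), bx])
    wx = x_mat * w[:, None]
    xtx = x_mat.T @ wx
    coef = np.linalg.solve(xtx, wx.T @ by)
    resid = by - x_mat @ coef
    q_prime = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q_prime / (j - 2)))
    cov = np.linalg.inv(xtx) * scale**2
    se = np.sqrt(np.diag(cov))
    p_slope = 2 * stats.t.sf(abs(coef[1] / se[1]), j - 2)
    p_int = 2 * stats.t.sf(abs(coef[0] / se[0]), j - 2)
    slope = MREstimate(
        "mr_egger", float(coef[1]), float(se[1]), float(p_slope), j, "random"
    )
    return EggerResult(slope, float(coef[0]), float(se[0]), float(p_int))


def cochran_q(hs: pd.DataFrame, estimate: MREstimate | EggerResult) -> HeterogeneityReport:
    """Heterogeneity of per-SNP estimates about a fitted MR model.

    For an IVW estimate: Cochran's Q = sum w_j (b_j - beta)^2, df = J - 1.
    For an Egger fit: Ruecker's Q' about the line with intercept, df = J - 2.
    """
    bx, _, by, sy = _arrays(hs)
    j = len(hs)
    if isinstance(estimate, EggerResult):
        if j < 4:
            raise InsufficientDataError("Egger Q' needs >= 4 instruments")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        resid = by * flip - (estimate.intercept + estimate.slope.beta * bx * flip)
        q = float(np.sum(resid**2 / sy**2))
        df = j - 2
        method = "egger"
    else:
        if j < 2:
            raise InsufficientDataError("Cochran's Q needs >= 2 instruments")
        w = bx**2 / sy**2
        ratios = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
        q = float(np.sum(w * (ratios - estimate.beta) ** 2))
        df = j - 1
        method = "ivw"
    return HeterogeneityReport(method, q, df, float(stats.chi2.sf(q, df)))


def _loo_betas(bx, by, sy):
    """Leave-one-out IVW betas, vectorized via sum subtraction."""
    w = 1.0 / sy**2
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx**2) - w * bx**2
    return num / den


def mr_presso(
    hs: pd.DataFrame, n_sim: int = 1000, seed: int = 0, alpha: float = 0.05
) -> PRESSOReport:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares RSS = sum w_j (Gamma_hat_j -
    beta_(-j) gamma_hat_j)^2 (leave-one-out IVW expectations, weights
    1/se_out^2) is compared against its parametric null distribution from
    ``n_sim`` simulations with Gamma*_j ~ N(beta_(-j) gamma_hat_j,
    se_out_j).  Per-SNP outlier p-values use the analogous per-SNP
    residual comparison with Bonferroni adjustment; flagged SNPs feed a
    distortion test comparing the estimate shift after outlier removal
    with the shift from removing random same-size SNP subsets.
    """
    j = len(hs)
    if j < 4:
        raise InsufficientDataError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise InvalidParameterError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    bx, _, by, sy = _arrays(hs)
    w = 1.0 / sy**2

    beta_loo = _loo_betas(bx, by, sy)
    expected = beta_loo * bx
    resid_obs = w * (by - expected) ** 2
    rss_obs = float(resid_obs.sum())

    # parametric simulations under the no-pleiotropy model
    sims = expected[None, :] + rng.normal(0.0, sy, size=(n_sim, j))
    w_bxby = w * bx * sims
    w_bx2 = w * bx**2
    num = w_bxby.sum(axis=1)[:, None] - w_bxby
    den = w_bx2.sum() - w_bx2
    beta_loo_sim = num / den[None, :]
    resid_sim = w * (sims - beta_loo_sim * bx) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    raw_p = (1 + (resid_sim >= resid_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    adj_p = np.minimum(raw_p * j, 1.0)
    snps = hs["snp"].to_numpy()
    outlier_p = pd.Series(adj_p, index=snps, name="outlier_p")
    # the outlier search is conditional on a significant global test
    if global_p < alpha:
        outliers = [str(s) for s, p in zip(snps, adj_p) if p < alpha]
    else:
        outliers = []

    beta_all = ivw(hs).beta
    beta_no = None
    distortion_p = None
    if outliers:
        keep = ~hs["snp"].isin(outliers).to_numpy()
        if keep.sum() >= 2:
            beta_no = ivw(hs[keep]).beta
            d_obs = (beta_all - beta_no) / beta_no
            n_perm = 1000
            d_null = np.empty(n_perm)
            k = len(outliers)
            for i in range(n_perm):
                drop = rng.choice(j, size=k, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                b_i = float(np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2))
                d_null[i] = (beta_all - b_i) / b_i
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_perm + 1))
    return PRESSOReport(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        distortion_p=distortion_p,
        beta_all=beta_all,
        beta_no_outliers=beta_no,
        n_sim=n_sim,
        seed=seed,
    )


def _huber_psi(t: np.ndarray, k: float = _HUBER_K) -> np.ndarray:
    return np.clip(t, -k, k)


def _huber_delta(k: float = _HUBER_K) -> float:
    # E[psi_k(Z)^2] for Z ~ N(0,1)
    phi_k = stats.norm.pdf(k)
    tail = stats.norm.sf(k)
    return (1 - 2 * tail) - 2 * k * phi_k + 2 * k**2 * tail


def mr_raps(
    hs: pd.DataFrame,
    overdispersion: bool = False,
    loss: str = "plain",
) -> MREstimate:
    """MR robust adjusted profile score estimate.

    Solves sum_j psi(t_j(beta)) dt_j/dbeta = 0 where
    t_j = (Gamma_hat_j - beta gamma_hat_j) / sqrt(se_out^2 + beta^2 se_exp^2
    + tau^2); psi is the identity (``loss='plain'``) or the Huber function
    with k = 1.345 (``loss='huber'``).  With ``overdispersion`` the
    systematic-pleiotropy variance tau^2 solves the companion moment
    condition sum(psi(t_j)^2 - delta) = 0 (floored at zero).  The SE is a
    sandwich estimate.  Returns the estimate; the fitted tau^2 is attached
    as attribute ``tau2``.
    """
    if len(hs) < 3:
        raise InsufficientDataError("MR-RAPS needs >= 3 instruments")
    if loss not in ("plain", "huber"):
        raise InvalidParameterError(f"unknown loss {loss!r}")
    bx, sx, by, sy = _arrays(hs)
    psi = _huber_psi if loss == "huber" else (lambda t: t)
    delta = _huber_delta() if loss == "huber" else 1.0

    def t_of(beta, tau2):
        s = np.sqrt(sy**2 + beta**2 * sx**2 + tau2)
        return (by - beta * bx) / s, s

    def score(beta, tau2):
        t, s = t_of(beta, tau2)
        dt = -bx / s - t * beta * sx**2 / s**2
        return float(np.sum(psi(t) * dt))

    def solve_beta(tau2, start):
        span = 0.5
        for _ in range(10):
            lo, hi = start - span, start + span
            f_lo, f_hi = score(lo, tau2), score(hi, tau2)
            if np.sign(f_lo) != np.sign(f_hi):
                return optimize.brentq(
                    lambda b: score(b, tau2), lo, hi, xtol=1e-12
                )
            span *= 2
        raise EstimationError("MR-RAPS: no sign change found for the profile score")

    def solve_tau2(beta):
        def moment(tau2):
            t, _ = t_of(beta, tau2)
            return float(np.sum(psi(t) ** 2 - delta))

        if moment(0.0) <= 0:
            return 0.0
        hi = 1.0
        while moment(hi) > 0 and hi < 1e6:
            hi *= 10
        return optimize.brentq(moment, 0.0, hi, xtol=1e-14)

    beta = ivw(hs).beta
    tau2 = 0.0
    for _ in range(200):
        beta_new = solve_beta(tau2, beta)
        tau2_new = solve_tau2(beta_new) if overdispersion else 0.0
        if abs(beta_new - beta) < 1e-12 and abs(tau2_new - tau2) < 1e-14:
            beta, tau2 = beta_new, tau2_new
            break
        beta, tau2 = beta_new, tau2_new

    # sandwich variance: B / A^2
    t, s = t_of(beta, tau2)
    dt = -bx / s - t * beta * sx**2 / s**2
    b_mat = float(np.sum(psi(t) ** 2 * dt**2))
    eps = 1e-6 * max(1.0, abs(beta))
    a_mat = (score(beta + eps, tau2) - score(beta - eps, tau2)) / (2 * eps)
    if a_mat == 0:
        raise EstimationError("MR-RAPS: degenerate score derivative")
    se = float(np.sqrt(b_mat) / abs(a_mat))
    p = 2 * stats.norm.sf(abs(beta) / se)
    est = MREstimate(
        "mr_raps", float(beta), se, float(p), len(hs),
        "overdispersed" if overdispersion else "fixed",
    )
    est.tau2 = tau2
    return est


@dataclass
class LeaveOneOutResult:
    estimates: pd.DataFrame  # snp, beta, se, p when that SNP is excluded
    flagged: list[str]  # exclusions that flip the sign or move beta > 1 SE
    full: MREstimate


def leave_one_out(hs: pd.DataFrame, model: str = "fixed") -> LeaveOneOutResult:
    """IVW recomputed excluding each SNP in turn, with influence flags."""
    if len(hs) < 3:
        raise InsufficientDataError("leave-one-out needs >= 3 instruments")
    full = ivw(hs, model=model)
    rows = []
    flagged = []
    for snp in hs["snp"]:
        sub = hs[hs["snp"] != snp]
        est = ivw(sub, model=model)
        rows.append({"snp": snp, "beta": est.beta, "se": est.se, "p": est.p})
        if np.sign(est.beta) != np.sign(full.beta) or abs(est.beta - full.beta) > full.se:
            flagged.append(str(snp))
    return LeaveOneOutResult(pd.DataFrame(rows), flagged, full)


@dataclass
class InstrumentStrengthReport:
    f_stats: pd.Series
    min_f: float
    mean_f: float
    n_strong: int  # count with F > 20
    threshold: float = 20.0


def instrument_strength(exposure: pd.DataFrame, threshold: float = 20.0) -> InstrumentStrengthReport:
    """Per-SNP F statistics (beta/se)^2 and the strong-instrument count."""
    se = exposure["se"].to_numpy(float)
    if np.any(se <= 0):
        raise InvalidParameterError("all SEs must be > 0")
    f = (exposure["beta"].to_numpy(float) / se) ** 2
    f_series = pd.Series(f, index=exposure["snp"].to_numpy(), name="F")
    return InstrumentStrengthReport(
        f_stats=f_series,
        min_f=float(f.min()),
        mean_f=float(f.mean()),
        n_strong=int(np.sum(f > threshold)),
        threshold=threshold,
    )
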