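"""Network Mendelian randomization: single-mediator effect decomposition.

Three pairwise two-sample MR fits are combined into the product-of-
coefficients mediation decomposition: alpha (exposure -> mediator, the
"action theory" path), beta (mediator -> outcome, the "conceptual
theory" path) and gamma (the total exposure -> outcome effect).  The
mediated (indirect) effect is alpha * beta and the mediated proportion
is alpha * beta / gamma, reported both as a fraction and as a truncated
integer percent.  A reverse-direction fit (mediator -> exposure, using
the mediator's instruments) serves as the bidirectionality check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mr
from .exceptions import InvalidParameterError

__all__ = ["MediationResult", "mediation", "run_network_mr", "NetworkMRReport"]


@dataclass
class MediationResult:
    alpha: float
    alpha_se: float
    beta_med: float
    beta_med_se: float
    gamma_total: float
    gamma_se: float
    indirect: float  # alpha * beta_med
    se_indirect: float  # first-order delta method
    proportion: float | None  # indirect / gamma_total
    proportion_pct: int | None  # truncated integer percent

    @property
    def direct(self) -> float:
        return self.gamma_total - self.indirect


def mediation(
    alpha: tuple[float, float],
    beta_med: tuple[float, float],
    gamma_total: tuple[float, float],
) -> MediationResult:
    """Product-of-coefficients mediation from three (effect, se) pairs.

    indirect = alpha * beta; proportion = alpha * beta / gamma (undefined
    and returned as None when gamma = 0);
    se_indirect = sqrt(beta^2 se_alpha^2 + alpha^2 se_beta^2).
    """
    a, se_a = alpha
    b, se_b = beta_med
    g, se_g = gamma_total
    if se_a < 0 or se_b < 0 or se_g < 0:
        raise InvalidParameterError("standard errors must be >= 0")
    indirect = a * b
    se_ind = math.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    if g == 0:
        prop, pct = None, None
    else:
        prop = indirect / g
        pct = math.trunc(prop * 100.0)
    return MediationResult(
        alpha=a,
        alpha_se=se_a,
        beta_med=b,
        beta_med_se=se_b,
        gamma_total=g,
        gamma_se=se_g,
        indirect=indirect,
        se_indirect=se_ind,
        proportion=prop,
        proportion_pct=pct,
    )


@dataclass
class NetworkMRReport:
    mediation: MediationResult
    edges: dict  # per-edge MREstimate
    reverse: mr.MREstimate  # mediator -> exposure bidirectionality check
    diagnostics: dict  # per-edge Q / Egger intercept / F panel


def _edge(
    instrument_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    instruments: np.ndarray | list[str],
    model: str,
) -> tuple[mr.MREstimate, dict, pd.DataFrame]:
    exp_sub = instrument_stats[instrument_stats["snp"].isin(instruments)]
    hs = mr.harmonize(exp_sub, outcome_stats)
    est = mr.ivw(hs, model=model)
    diag = {
        "q": mr.cochran_q(hs, est),
        "egger": mr.mr_egger(hs) if len(hs) >= 3 else None,
        "f": mr.instrument_strength(exp_sub),
        "n_snp": len(hs),
    }
    return est, diag, hs


def run_network_mr(
    exposure_stats: pd.DataFrame,
    mediator_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    exposure_instruments,
    mediator_instruments,
    model: str = "fixed",
) -> NetworkMRReport:
    """Chain three IVW fits into the mediation decomposition.

    The three tables give, for one shared SNP panel, each SNP's
    association with the exposure, the mediator, and the outcome.  The
    exposure's instruments identify alpha (exposure -> mediator) and
    gamma (exposure -> outcome); the mediator's instruments identify
    beta (mediator -> outcome) and the reverse edge (mediator ->
    exposure) used as the bidirectionality check.  Heterogeneity (Q),
    Egger-intercept and instrument-strength diagnostics are attached to
    every edge.
    """
    alpha_est, d_alpha, _ = _edge(exposure_stats, mediator_stats, exposure_instruments, model)
    gamma_est, d_gamma, _ = _edge(exposure_stats, outcome_stats, exposure_instruments, model)
    beta_est, d_beta, _ = _edge(mediator_stats, outcome_stats, mediator_instruments, model)
    reverse_est, d_rev, _ = _edge(mediator_stats, exposure_stats, mediator_instruments, model)
    med = mediation(
        (alpha_est.beta, alpha_est.se),
        (beta_est.beta, beta_est.se),
        (gamma_est.beta, gamma_est.se),
    )
    return NetworkMRReport(
        mediation=med,
        edges={"alpha": alpha_est, "beta": beta_est, "gamma": gamma_est},
        reverse=reverse_est,
        diagnostics={"alpha": d_alpha, "beta": d_beta, "gamma": d_gamma, "reverse": d_rev},
    )
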