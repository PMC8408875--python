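"""Synthetic cohort and GWAS summary-statistics generators with known truth.

The cohort generator emulates a ~1000-person sequential-mixed-meal study:
two-peak glucose curves (breakfast at 0 min, lunch at 240 min), a late
single-peak triglyceride curve, GlycA measured at 0/4/6 h that is strongly
coupled to the TG response and weakly to the glucose response, an IL-6
rise that is independent of the meal responses, and a planted
VFM -> fasting TG -> GlycA path structure.  All planted coefficients are
recorded in a truth record so downstream estimators can be tested for
recovery.

The GWAS generator emits two-sample summary statistics (per-SNP exposure
and outcome associations) with a planted causal effect, optional
directional or balanced pleiotropy, and optional outlier instruments; a
three-trait variant plants an exposure -> mediator -> outcome chain for
network-MR tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import PostprandialCurve, curve_model
from .exceptions import ConfigError

__all__ = [
    "CohortSimConfig",
    "CohortDataset",
    "MRSimConfig",
    "NetworkMRSimConfig",
    "simulate_cohort",
    "simulate_two_sample_gwas",
    "simulate_network_gwas",
]

#: Sampling grid (minutes) of the emulated clinic day.
DEFAULT_SAMPLING_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0, 270.0, 300.0, 360.0)

_CONC_FLOOR = 0.01  # concentrations are clipped to stay positive


@dataclass
class CohortSimConfig:
    """Configuration of the synthetic postprandial cohort.

    Effects are standardized slopes (per SD of the source variable, in SDs
    of the target); noise SDs for the markers are likewise in standardized
    (latent) units and scaled by the marker's scale parameter.
    """

    n_participants: int = 1000
    seed: int = 0
    # glucose: baseline ~ N(4.91, 0.51) mmol/L, breakfast peak at 30 min,
    # lunch peak at 300 min (amplitude mmol/L, peak-time min, width min)
    glucose_baseline: tuple[float, float] = (4.91, 0.51)
    glucose_curve_params: tuple[tuple[float, float, float], ...] = (
        (2.60, 40.0, 16.0),
        (1.56, 300.0, 35.0),
    )
    glucose_amp_sd: tuple[float, ...] = (1.20, 1.40)
    # TG: baseline ~ N(1.05, 0.53) mmol/L, single late peak
    tg_baseline: tuple[float, float] = (1.05, 0.53)
    tg_curve_params: tuple[tuple[float, float, float], ...] = ((1.12, 290.0, 80.0),)
    tg_amp_sd: tuple[float, ...] = (0.85,)
    # planted standardized path structure
    effect_vfm_on_tg: float = 0.30
    effect_tg_on_glyca: float = 0.70
    effect_glucose_on_glyca: float = 0.15
    effect_vfm_direct_on_glyca: float = 0.17
    effect_fasting_glyca_on_glyca6h: float = 0.30
    # markers: GlycA location/scale (mmol/L); IL-6 in opaque marker units
    glyca_mean: float = 1.32
    glyca_scale: float = 0.18
    il6_fasting: tuple[float, float] = (0.41, 0.28)
    il6_rise_4h: tuple[float, float] = (0.45, 0.35)
    il6_rise_6h: tuple[float, float] = (0.81, 0.50)
    # per-marker latent residual SDs and per-sample curve measurement noise
    noise_sd: dict = field(
        default_factory=lambda: {
            "glyca_fasting": 0.55,
            "glyca_6h": 0.45,
            "glyca_4h": 0.20,
            "glucose": 0.04,
            "tg": 0.03,
        }
    )
    # covariates
    age_range: tuple[float, float] = (18.0, 65.0)
    female_fraction: float = 0.72
    bmi: tuple[float, float] = (25.6, 5.0)
    weight: tuple[float, float] = (72.9, 15.3)
    vfm: tuple[float, float] = (1.00, 0.35)
    microbiome_pc_sds: tuple[float, ...] = tuple(0.8**k for k in range(10))
    # sex structure: level shifts (marker units) and an optional
    # sex-specific 6-h rise (standardized units, applied to females)
    il6_female_level_shift: float = 0.10
    glyca_male_level_shift: float = 0.05
    sex_specific_rise: dict = field(default_factory=lambda: {"glyca": 0.0, "il6": 0.0})
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        times = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ConfigError("sampling_times must be strictly increasing")
        for required in (0.0, 240.0, 360.0):
            if not np.any(np.isclose(times, required)):
                raise ConfigError(f"sampling_times must include {required} min")
        sds = (
            [self.glucose_baseline[1], self.tg_baseline[1], self.glyca_scale]
            + list(self.glucose_amp_sd)
            + list(self.tg_amp_sd)
            + list(self.noise_sd.values())
            + list(self.microbiome_pc_sds)
        )
        if any(s < 0 for s in sds):
            raise ConfigError("all SDs must be >= 0")


@dataclass
class CohortDataset:
    """Simulated cohort: curves, 0/4/6-h marker series, covariates, truth."""

    curves: list[PostprandialCurve]
    markers: pd.DataFrame  # long: participant_id, marker, time_h, value
    covariates: pd.DataFrame  # one row per participant
    truth: dict

    def curves_for(self, analyte: str) -> list[PostprandialCurve]:
        return [c for c in self.curves if c.analyte == analyte]

    def marker_wide(self, marker: str) -> pd.DataFrame:
        """Wide 0/4/6-h table for one marker, indexed by participant."""
        sub = self.markers[self.markers["marker"] == marker]
        wide = sub.pivot(index="participant_id", columns="time_h", values="value")
        wide.columns = [f"value_{int(c)}h" for c in wide.columns]
        return wide


def _draw_amplitudes(rng, means_params, sds, n):
    """Per-participant peak amplitudes, truncated at zero."""
    amps = np.empty((n, len(means_params)))
    for k, ((amp_mean, _, _), sd) in enumerate(zip(means_params, sds)):
        amps[:, k] = np.maximum(rng.normal(amp_mean, sd, size=n), 0.0)
    return amps


def simulate_cohort(config: CohortSimConfig | None = None) -> CohortDataset:
    """Simulate a postprandial cohort with a planted linear path structure.

    The generative model, per participant i (z denotes standardization by
    the realized value's population location/scale):

    * VFM, age, sex, BMI, weight, microbiome PCs drawn independently.
    * fasting TG latent z_TG = b_VT z_VFM + sqrt(1 - b_VT^2) e, so the
      marginal variance stays 1 while the VFM -> TG path is planted.
    * glucose and TG curves: participant baseline + participant-level peak
      amplitudes on the configured Gaussian-peak shapes, plus per-sample
      measurement noise, clipped positive.
    * fasting GlycA = mean + scale * (b_TG z_TG + b_VFM z_VFM + noise).
    * 6-h GlycA = mean6 + scale * (b_FG z_fastGlycA + b_TG z_TG6h
      + b_Glu z_Glumax1 + noise), where TG6h and Glumax1 are the realized
      curve features - postprandial GlycA is coupled to the realized meal
      response, strongly via TG and weakly via glucose.
    * IL-6 at 4/6 h = fasting + configured rise + noise, independent of
      every meal-response quantity.

    Deterministic for a fixed config and seed.
    """
    cfg = config or CohortSimConfig()
    cfg.validate()
    n = cfg.n_participants
    root = np.random.default_rng(cfg.seed)
    # named sub-streams so each block of draws is independent
    r_cov, r_glu, r_tg, r_glyca, r_il6 = root.spawn(5)

    times = np.asarray(cfg.sampling_times, dtype=float)
    pid = np.array([f"P{i:04d}" for i in range(n)])

    # --- covariates ---------------------------------------------------
    age = r_cov.uniform(*cfg.age_range, size=n)
    sex = (r_cov.random(n) < cfg.female_fraction).astype(int)  # 1 = female
    bmi = r_cov.normal(*cfg.bmi, size=n)
    weight = np.maximum(r_cov.normal(*cfg.weight, size=n), 30.0)
    vfm = np.maximum(r_cov.normal(*cfg.vfm, size=n), 0.05)
    z_vfm = (vfm - cfg.vfm[0]) / cfg.vfm[1]
    pcs = {
        f"microbiome_pc{k + 1}": r_cov.normal(0.0, sd, size=n)
        for k, sd in enumerate(cfg.microbiome_pc_sds)
    }

    # --- fasting TG with the planted VFM path -------------------------
    b_vt = cfg.effect_vfm_on_tg
    z_tg_lat = b_vt * z_vfm + np.sqrt(max(0.0, 1.0 - b_vt**2)) * r_tg.standard_normal(n)
    tg_fasting = np.maximum(cfg.tg_baseline[0] + cfg.tg_baseline[1] * z_tg_lat, _CONC_FLOOR)
    z_tg = (tg_fasting - cfg.tg_baseline[0]) / cfg.tg_baseline[1]

    # --- curves --------------------------------------------------------
    glu_base = np.maximum(r_glu.normal(*cfg.glucose_baseline, size=n), 1.0)
    glu_amp = _draw_amplitudes(r_glu, cfg.glucose_curve_params, cfg.glucose_amp_sd, n)
    tg_amp = _draw_amplitudes(r_tg, cfg.tg_curve_params, cfg.tg_amp_sd, n)

    curves: list[PostprandialCurve] = []
    glu_noise = r_glu.normal(0.0, cfg.noise_sd["glucose"], size=(n, times.size))
    tg_noise = r_tg.normal(0.0, cfg.noise_sd["tg"], size=(n, times.size))
    glu_values = np.empty((n, times.size))
    tg_values = np.empty((n, times.size))
    for i in range(n):
        peaks_g = [
            (glu_amp[i, k], pt, w) for k, (_, pt, w) in enumerate(cfg.glucose_curve_params)
        ]
        peaks_t = [
            (tg_amp[i, k], pt, w) for k, (_, pt, w) in enumerate(cfg.tg_curve_params)
        ]
        glu_values[i] = np.maximum(
            curve_model(times, peaks_g, glu_base[i]) + glu_noise[i], _CONC_FLOOR
        )
        tg_values[i] = np.maximum(
            curve_model(times, peaks_t, tg_fasting[i]) + tg_noise[i], _CONC_FLOOR
        )
        curves.append(PostprandialCurve(pid[i], "glucose", times, glu_values[i]))
        curves.append(PostprandialCurve(pid[i], "tg", times, tg_values[i]))

    # realized meal-response features entering the GlycA model
    i360 = int(np.flatnonzero(np.isclose(times, 360.0))[0])
    tg_at_6h = tg_values[:, i360]
    win = (times >= 0.0) & (times <= 120.0)
    glu_max1 = glu_values[:, win].max(axis=1)

    # standardization anchors for the realized features: the population
    # mean/SD implied by the peak shapes at the relevant grid time
    def _shapes(params, at):
        return np.array(
            [np.exp(-((at - pt) ** 2) / (2 * w**2)) for (_, pt, w) in params]
        )

    s_tg360 = _shapes(cfg.tg_curve_params, 360.0)
    tg_amp_means = np.array([a for a, _, _ in cfg.tg_curve_params])
    tg6_mean = cfg.tg_baseline[0] + float(tg_amp_means @ s_tg360)
    tg6_sd = float(
        np.sqrt(cfg.tg_baseline[1] ** 2 + np.sum((np.array(cfg.tg_amp_sd) * s_tg360) ** 2))
    )
    glu_amp_means = np.array([a for a, _, _ in cfg.glucose_curve_params])
    mean_curve = np.array(
        [cfg.glucose_baseline[0] + glu_amp_means @ _shapes(cfg.glucose_curve_params, t) for t in times]
    )
    t_star = times[win][np.argmax(mean_curve[win])]
    s_gmax = _shapes(cfg.glucose_curve_params, t_star)
    gmax_mean = cfg.glucose_baseline[0] + float(glu_amp_means @ s_gmax)
    gmax_sd = float(
        np.sqrt(
            cfg.glucose_baseline[1] ** 2
            + np.sum((np.array(cfg.glucose_amp_sd) * s_gmax) ** 2)
        )
    )
    z_tg6 = (tg_at_6h - tg6_mean) / tg6_sd
    z_gmax = (glu_max1 - gmax_mean) / gmax_sd

    # --- GlycA at 0/4/6 h ----------------------------------------------
    male = 1 - sex
    glyca_fast = cfg.glyca_mean + cfg.glyca_scale * (
        cfg.effect_tg_on_glyca * z_tg
        + cfg.effect_vfm_direct_on_glyca * z_vfm
        + cfg.noise_sd["glyca_fasting"] * r_glyca.standard_normal(n)
    ) + cfg.glyca_male_level_shift * male
    glyca_fast = np.maximum(glyca_fast, _CONC_FLOOR)
    z_gf = (glyca_fast - cfg.glyca_mean) / cfg.glyca_scale

    glyca_6h = (
        cfg.glyca_mean
        + 0.06  # mean postprandial shift
        + cfg.glyca_scale
        * (
            cfg.effect_fasting_glyca_on_glyca6h * z_gf
            + cfg.effect_tg_on_glyca * z_tg6
            + cfg.effect_glucose_on_glyca * z_gmax
            + cfg.noise_sd["glyca_6h"] * r_glyca.standard_normal(n)
            + cfg.sex_specific_rise["glyca"] * sex
        )
        + cfg.glyca_male_level_shift * male
    )
    glyca_6h = np.maximum(glyca_6h, _CONC_FLOOR)
    glyca_4h = np.maximum(
        glyca_fast
        + 0.5 * (glyca_6h - glyca_fast)
        + cfg.glyca_scale * cfg.noise_sd["glyca_4h"] * r_glyca.standard_normal(n),
        _CONC_FLOOR,
    )

    # --- IL-6 at 0/4/6 h: meal-independent rise ------------------------
    il6_fast = np.maximum(
        r_il6.normal(*cfg.il6_fasting, size=n) + cfg.il6_female_level_shift * sex,
        _CONC_FLOOR,
    )
    il6_4h = np.maximum(il6_fast + r_il6.normal(*cfg.il6_rise_4h, size=n), _CONC_FLOOR)
    il6_6h = np.maximum(
        il6_fast
        + r_il6.normal(*cfg.il6_rise_6h, size=n)
        + cfg.sex_specific_rise["il6"] * sex,
        _CONC_FLOOR,
    )

    markers = pd.DataFrame(
        {
            "participant_id": np.tile(pid, 6),
            "marker": np.repeat(["glyca", "il6"], 3 * n),
            "time_h": np.concatenate(
                [np.repeat([0, 4, 6], n), np.repeat([0, 4, 6], n)]
            ),
            "value": np.concatenate(
                [glyca_fast, glyca_4h, glyca_6h, il6_fast, il6_4h, il6_6h]
            ),
        }
    )
    covariates = pd.DataFrame(
        {
            "participant_id": pid,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "weight": weight,
            "vfm": vfm,
            "tg_fasting": tg_fasting,
            **pcs,
        }
    )
    truth = {
        "standardized": {
            "vfm_on_tg": cfg.effect_vfm_on_tg,
            "tg_on_glyca": cfg.effect_tg_on_glyca,
            "glucose_on_glyca": cfg.effect_glucose_on_glyca,
            "vfm_direct_on_glyca": cfg.effect_vfm_direct_on_glyca,
            "fasting_glyca_on_glyca6h": cfg.effect_fasting_glyca_on_glyca6h,
        },
        # raw regression slopes implied by the construction (exact in the
        # zero-noise limit): d glyca_fast / d tg_fasting etc.
        "raw": {
            "tg_on_glyca_fasting": cfg.effect_tg_on_glyca
            * cfg.glyca_scale
            / cfg.tg_baseline[1],
            "vfm_on_glyca_fasting": cfg.effect_vfm_direct_on_glyca
            * cfg.glyca_scale
            / cfg.vfm[1],
        },
        "feature_scales": {
            "tg_at_6h": (tg6_mean, tg6_sd),
            "glu_max1": (gmax_mean, gmax_sd),
        },
    }
    return CohortDataset(curves=curves, markers=markers, covariates=covariates, truth=truth)


# ----------------------------------------------------------------------
# two-sample GWAS summary statistics
# ----------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SUMMARY_STAT_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]


@dataclass
class MRSimConfig:
    """Configuration of the two-sample GWAS summary-statistics generator."""

    n_snps: int = 50
    n_exposure_sample: int = 300_000
    n_outcome_sample: int = 100_000
    causal_beta: float = 0.2
    instrument_strength: tuple[float, float] = (0.08, 0.02)  # true gamma mean, sd
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_effect: float = 0.0
    palindromic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.n_exposure_sample < 2 or self.n_outcome_sample < 2:
            raise ConfigError("sample sizes must be >= 2")
        if not 0 <= self.n_outliers <= self.n_snps:
            raise ConfigError("n_outliers must lie in [0, n_snps]")


def _allele_pairs(rng, n, palindromic_fraction):
    """Random biallelic pairs; optionally a fraction are strand-ambiguous."""
    eff = np.empty(n, dtype="<U1")
    oth = np.empty(n, dtype="<U1")
    is_pal = rng.random(n) < palindromic_fraction
    for j in range(n):
        a = _BASES[rng.integers(4)]
        if is_pal[j]:
            b = _COMPLEMENT[a]
        else:
            choices = [x for x in _BASES if x != a and x != _COMPLEMENT[a]]
            b = choices[rng.integers(len(choices))]
        eff[j], oth[j] = a, b
    return eff, oth


def _assoc_table(rng, snp, eff, oth, eaf, true_beta, se, n_sample):
    from scipy import stats

    beta_hat = true_beta + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
    return pd.DataFrame(
        {
            "snp": snp,
            "effect_allele": eff,
            "other_allele": oth,
            "eaf": eaf,
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "n": n_sample,
        }
    )


def simulate_two_sample_gwas(
    config: MRSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate exposure and outcome summary-statistics tables.

    Per SNP j: true instrument effect gamma_j ~ N(instrument_strength);
    the exposure estimate adds noise with SE 1/sqrt(2 p_j (1-p_j) n_exp)
    (per-allele effect on a standardized trait).  The true outcome effect
    is ``causal_beta * gamma_j + pleiotropy_j``, plus ``outlier_effect``
    for the first ``n_outliers`` SNPs; the outcome estimate adds noise
    with the analogous outcome-sample SE.  Returns (exposure, outcome)
    tables with columns snp/effect_allele/other_allele/eaf/beta/se/pval/n.
    """
    cfg = config or MRSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    snp = np.array([f"rs{1000 + k}" for k in range(j)])
    eff, oth = _allele_pairs(rng, j, cfg.palindromic_fraction)
    eaf = rng.uniform(0.05, 0.95, size=j)

    gamma = rng.normal(*cfg.instrument_strength, size=j)
    var_g = 2.0 * eaf * (1.0 - eaf)
    se_exp = 1.0 / np.sqrt(var_g * cfg.n_exposure_sample)
    se_out = 1.0 / np.sqrt(var_g * cfg.n_outcome_sample)

    pleio = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=j) if (
        cfg.pleiotropy_mean != 0.0 or cfg.pleiotropy_sd != 0.0
    ) else np.zeros(j)
    big_gamma = cfg.causal_beta * gamma + pleio
    if cfg.n_outliers:
        big_gamma[: cfg.n_outliers] += cfg.outlier_effect

    exposure = _assoc_table(rng, snp, eff, oth, eaf, gamma, se_exp, cfg.n_exposure_sample)
    outcome = _assoc_table(rng, snp, eff, oth, eaf, big_gamma, se_out, cfg.n_outcome_sample)
    return exposure, outcome


@dataclass
class NetworkMRSimConfig:
    """Three-trait GWAS generator for a planted mediation chain.

    Exposure instruments (J_exp SNPs) act on the exposure; mediator
    instruments (J_med SNPs) act directly on the mediator.  With planted
    paths ``alpha`` (exposure -> mediator), ``beta_med`` (mediator ->
    outcome) and ``direct_effect`` (exposure -> outcome, not via the
    mediator), the implied per-SNP effects are

    * exposure trait: gamma_j for exposure instruments, 0 for mediator ones
      (the mediator does not cause the exposure);
    * mediator trait: alpha*gamma_j and kappa_k respectively;
    * outcome trait: (alpha*beta_med + direct_effect)*gamma_j and
      beta_med*kappa_k respectively.
    """

    n_exposure_snps: int = 50
    n_mediator_snps: int = 50
    alpha: float = 0.13
    beta_med: float = 0.49
    direct_effect: float = 0.1563  # total = alpha*beta_med + direct
    instrument_strength: tuple[float, float] = (0.08, 0.02)
    n_sample: int = 300_000
    seed: int = 0

    @property
    def total_effect(self) -> float:
        return self.alpha * self.beta_med + self.direct_effect


def simulate_network_gwas(
    config: NetworkMRSimConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary statistics for exposure, mediator and outcome over one SNP panel.

    Returns a dict with keys ``exposure``, ``mediator``, ``outcome``; each
    table covers all exposure + mediator instruments so any pairwise edge
    can be harmonized and estimated.
    """
    cfg = config or NetworkMRSimConfig()
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_exposure_snps + cfg.n_mediator_snps
    snp = np.array([f"rs{1000 + k}" for k in range(j)])
    eff, oth = _allele_pairs(rng, j, 0.0)
    eaf = rng.uniform(0.05, 0.95, size=j)
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_sample)

    is_exp = np.arange(j) < cfg.n_exposure_snps
    strength = rng.normal(*cfg.instrument_strength, size=j)
    beta_on_exp = np.where(is_exp, strength, 0.0)
    beta_on_med = np.where(is_exp, cfg.alpha * strength, strength)
    beta_on_out = np.where(
        is_exp, cfg.total_effect * strength, cfg.beta_med * strength
    )
    tables = {}
    for name, true_beta in (
        ("exposure", beta_on_exp),
        ("mediator", beta_on_med),
        ("outcome", beta_on_out),
    ):
        tables[name] = _assoc_table(rng, snp, eff, oth, eaf, true_beta, se, cfg.n_sample)
    tables["exposure_instruments"] = snp[is_exp]
    tables["mediator_instruments"] = snp[~is_exp]
    return tables
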