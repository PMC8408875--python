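"""Two-sample MR estimators: harmonization, IVW, Egger, Q, PRESSO, RAPS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import postmeal as pm
from postmeal import mr
from postmeal.exceptions import (
    EstimationError,
    InsufficientDataError,
    InvalidParameterError,
)


def assoc(snp, ea, oa, eaf, beta, se, n=100_000):
    return {
        "snp": snp, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pval": 2 * stats.norm.sf(abs(beta) / se), "n": n,
    }


def make_hs(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, float)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(bx))],
            "beta_exp": bx,
            "se_exp": sx,
            "beta_out": np.asarray(by, float),
            "se_out": np.asarray(sy, float),
        }
    )


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = pd.DataFrame([assoc("rs1", "A", "G", 0.3, 0.1, 0.01)])
        out = pd.DataFrame([assoc("rs1", "G", "A", 0.7, -0.05, 0.01)])
        hs = pm.harmonize(exp, out)
        assert hs["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_identical_alleles_unchanged(self):
        exp = pd.DataFrame([assoc("rs1", "A", "G", 0.3, 0.1, 0.01)])
        out = pd.DataFrame([assoc("rs1", "A", "G", 0.3, 0.07, 0.01)])
        hs = pm.harmonize(exp, out)
        assert hs["beta_out"].iloc[0] == pytest.approx(0.07)

    def test_ambiguous_palindromic_dropped(self):
        exp = pd.DataFrame(
            [assoc("rs1", "A", "T", 0.50, 0.1, 0.01), assoc("rs2", "A", "G", 0.3, 0.1, 0.01)]
        )
        out = pd.DataFrame(
            [assoc("rs1", "A", "T", 0.50, 0.1, 0.01), assoc("rs2", "A", "G", 0.3, 0.1, 0.01)]
        )
        hs = pm.harmonize(exp, out)
        assert list(hs["snp"]) == ["rs2"]

    def test_palindromic_outside_window_kept(self):
        exp = pd.DataFrame([assoc("rs1", "A", "T", 0.10, 0.1, 0.01)])
        out = pd.DataFrame([assoc("rs1", "A", "T", 0.10, 0.1, 0.01)])
        assert len(pm.harmonize(exp, out)) == 1

    def test_incompatible_alleles_dropped(self):
        exp = pd.DataFrame(
            [assoc("rs1", "A", "G", 0.3, 0.1, 0.01), assoc("rs2", "C", "T", 0.4, 0.1, 0.01)]
        )
        out = pd.DataFrame(
            [assoc("rs1", "A", "C", 0.3, 0.1, 0.01), assoc("rs2", "C", "T", 0.4, 0.1, 0.01)]
        )
        assert list(pm.harmonize(exp, out)["snp"]) == ["rs2"]

    def test_empty_intersection_rejected(self):
        exp = pd.DataFrame([assoc("rs1", "A", "G", 0.3, 0.1, 0.01)])
        out = pd.DataFrame([assoc("rs2", "A", "G", 0.3, 0.1, 0.01)])
        with pytest.raises(InsufficientDataError):
            pm.harmonize(exp, out)


class TestWaldRatio:
    def test_direct_ratio(self):
        hs = make_hs([0.1], [0.05], [0.01])
        est = pm.wald_ratio(hs)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        assert pm.wald_ratio(make_hs([0.1], [0.0], [0.01])).beta == 0.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(EstimationError):
            pm.wald_ratio(make_hs([0.0], [0.05], [0.01]))

    def test_second_order_se_matches_bootstrap_oracle(self):
        """At gamma/se_exp = 10 the delta-method SE with the exposure term
        tracks the Monte-Carlo SD of the ratio within 5%."""
        gamma, sx = 0.1, 0.01
        big_gamma, sy = 0.05, 0.01
        rng = np.random.default_rng(3)
        n = 1_000_000
        draws = rng.normal(big_gamma, sy, n) / rng.normal(gamma, sx, n)
        mc_sd = draws.std()
        hs = make_hs([gamma], [big_gamma], [sy], [sx])
        est = pm.wald_ratio(hs, second_order=True)
        assert est.se == pytest.approx(mc_sd, rel=0.05)


class TestIVW:
    def test_single_snp_equals_wald(self):
        hs = make_hs([0.1], [0.05], [0.01])
        assert pm.ivw(hs).beta == pm.wald_ratio(hs).beta
        assert pm.ivw(hs).se == pm.wald_ratio(hs).se

    def test_symmetric_average(self):
        hs = make_hs([0.1, 0.1], [0.04, 0.06], [0.01, 0.01])
        assert pm.ivw(hs).beta == pytest.approx(0.5)

    def test_equals_grid_search_oracle(self, clean_harmonized):
        hs = clean_harmonized
        w = 1.0 / hs["se_out"] ** 2
        grid = np.linspace(-2, 2, 400_001)
        loss = [
            float(np.sum(w * (hs["beta_out"] - b * hs["beta_exp"]) ** 2))
            for b in grid[::400]
        ]
        coarse = grid[::400][int(np.argmin(loss))]
        fine = np.linspace(coarse - 0.01, coarse + 0.01, 20_001)
        loss = [
            float(np.sum(w * (hs["beta_out"] - b * hs["beta_exp"]) ** 2)) for b in fine
        ]
        oracle = fine[int(np.argmin(loss))]
        assert pm.ivw(hs).beta == pytest.approx(oracle, abs=2e-6)

    def test_snp_order_invariance(self, clean_harmonized):
        shuffled = clean_harmonized.sample(frac=1.0, random_state=0)
        assert pm.ivw(shuffled).beta == pytest.approx(pm.ivw(clean_harmonized).beta)

    def test_reorienting_a_snp_leaves_estimators_unchanged(self, clean_harmonized):
        flipped = clean_harmonized.copy()
        flipped.loc[flipped.index[:10], ["beta_exp", "beta_out"]] *= -1
        assert pm.ivw(flipped).beta == pytest.approx(pm.ivw(clean_harmonized).beta)
        assert pm.mr_egger(flipped).slope.beta == pytest.approx(
            pm.mr_egger(clean_harmonized).slope.beta
        )
        assert pm.mr_raps(flipped).beta == pytest.approx(
            pm.mr_raps(clean_harmonized).beta, abs=1e-9
        )

    def test_random_effects_inflates_se_under_heterogeneity(self):
        hs = make_hs([0.1] * 6, [0.02, 0.03, 0.08, 0.04, 0.09, 0.01], [0.005] * 6)
        assert pm.ivw(hs, model="random").se > pm.ivw(hs, model="fixed").se


class TestEgger:
    def test_too_few_instruments_rejected(self):
        with pytest.raises(InsufficientDataError):
            pm.mr_egger(make_hs([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_zero_intercept_mode_equals_fixed_ivw(self, clean_harmonized):
        constrained = pm.mr_egger(clean_harmonized, fit_intercept=False)
        est = pm.ivw(clean_harmonized, model="fixed")
        assert constrained.slope.beta == pytest.approx(est.beta, abs=1e-12)
        assert constrained.slope.se == pytest.approx(est.se, abs=1e-12)

    def test_intercept_size_under_null(self):
        """With no pleiotropy the intercept test rejects at ~5%."""
        reject = 0
        reps = 200
        for i in range(reps):
            cfg = pm.MRSimConfig(n_snps=50, causal_beta=0.3, seed=70_000 + i)
            hs = pm.harmonize(*pm.simulate_two_sample_gwas(cfg))
            reject += pm.mr_egger(hs).intercept_p < 0.05
        assert 0.01 <= reject / reps <= 0.10


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        hs = make_hs([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.01, 0.01])
        rep = pm.cochran_q(hs, pm.ivw(hs))
        assert rep.statistic == pytest.approx(0.0, abs=1e-20)
        assert rep.p == pytest.approx(1.0)

    def test_null_distribution_uniform(self):
        """Homogeneous simulations: Q/df near 1 and p-values uniform."""
        rng = np.random.default_rng(13)
        stats_, ps = [], []
        for _ in range(1000):
            bx = rng.normal(0.1, 0.02, 30)
            sy = np.full(30, 0.01)
            by = 0.4 * bx + rng.normal(0, sy)
            hs = make_hs(bx, by, sy)
            rep = pm.cochran_q(hs, pm.ivw(hs))
            stats_.append(rep.statistic / rep.df)
            ps.append(rep.p)
        assert np.mean(stats_) == pytest.approx(1.0, abs=0.05)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_planted_outlier(self):
        rng = np.random.default_rng(14)
        hits = 0
        reps = 100
        for _ in range(reps):
            bx = rng.normal(0.1, 0.02, 30)
            sy = np.full(30, 0.01)
            by = 0.4 * bx + rng.normal(0, sy)
            by[0] += 10 * sy[0]
            rep = pm.cochran_q(make_hs(bx, by, sy), pm.ivw(make_hs(bx, by, sy)))
            hits += rep.p < 0.001
        assert hits / reps >= 0.99

    def test_egger_q_prime_df(self, clean_harmonized):
        rep = pm.cochran_q(clean_harmonized, pm.mr_egger(clean_harmonized))
        assert rep.df == len(clean_harmonized) - 2


class TestPRESSO:
    def test_deterministic_given_seed(self, clean_harmonized):
        a = pm.mr_presso(clean_harmonized, n_sim=200, seed=5)
        b = pm.mr_presso(clean_harmonized, n_sim=200, seed=5)
        assert a.global_p == b.global_p
        assert a.outliers == b.outliers

    def test_preconditions(self, clean_harmonized):
        with pytest.raises(InsufficientDataError):
            pm.mr_presso(clean_harmonized.head(3))
        with pytest.raises(InvalidParameterError):
            pm.mr_presso(clean_harmonized, n_sim=10)

    def test_flags_gross_outlier_and_reports_distortion(self, clean_harmonized):
        hs = clean_harmonized.copy().reset_index(drop=True)
        hs.loc[0, "beta_out"] += 12 * hs.loc[0, "se_out"]
        # n_sim must exceed J/alpha for the Bonferroni-adjusted per-SNP
        # p-value floor (J/(n_sim+1)) to clear alpha
        rep = pm.mr_presso(hs, n_sim=2000, seed=2)
        assert hs.loc[0, "snp"] in rep.outliers
        assert rep.distortion_p is not None
        assert rep.beta_no_outliers is not None


class TestRAPS:
    def test_reduces_to_ivw_without_exposure_noise(self):
        rng = np.random.default_rng(6)
        bx = rng.normal(0.1, 0.02, 30)
        sy = np.full(30, 0.01)
        by = 0.4 * bx + rng.normal(0, sy)
        hs = make_hs(bx, by, sy, sx=np.full(30, 1e-10))
        assert pm.mr_raps(hs).beta == pytest.approx(pm.ivw(hs).beta, abs=1e-8)

    def test_overdispersion_recovery(self):
        """Planted tau^2 = 0.01 is recovered (median within [0.005, 0.02])."""
        rng = np.random.default_rng(8)
        taus = []
        for _ in range(200):
            j = 100
            bx = rng.normal(0.1, 0.02, j)
            sx = np.full(j, 0.002)
            sy = np.full(j, 0.01)
            pleio = rng.normal(0.0, 0.1, j)  # tau = 0.1 -> tau^2 = 0.01
            by = 0.4 * bx + pleio + rng.normal(0, sy)
            bxh = bx + rng.normal(0, sx)
            est = pm.mr_raps(make_hs(bxh, by, sy, sx), overdispersion=True)
            taus.append(est.tau2)
        assert 0.005 <= float(np.median(taus)) <= 0.02

    def test_huber_loss_available(self, clean_harmonized):
        est = pm.mr_raps(clean_harmonized, loss="huber")
        ivw_est = pm.ivw(clean_harmonized)
        assert est.beta == pytest.approx(ivw_est.beta, abs=3 * ivw_est.se)

    def test_estimators_agree_in_clean_regime(self, clean_harmonized):
        """IVW, Egger, RAPS and PRESSO-corrected IVW coincide without
        pleiotropy (within joint uncertainty)."""
        hs = clean_harmonized
        ivw_est = pm.ivw(hs)
        egger = pm.mr_egger(hs)
        raps = pm.mr_raps(hs)
        presso = pm.mr_presso(hs, n_sim=200, seed=1)
        tol = 2 * max(ivw_est.se, egger.slope.se, raps.se)
        for other in (egger.slope.beta, raps.beta, presso.beta_all):
            assert abs(other - ivw_est.beta) < tol


class TestLeaveOneOut:
    def test_cardinality(self, clean_harmonized):
        res = pm.leave_one_out(clean_harmonized.head(3))
        assert len(res.estimates) == 3

    def test_homogeneous_instruments_unflagged(self):
        hs = make_hs([0.1, 0.2, 0.3, 0.4], [0.05, 0.10, 0.15, 0.20], [0.01] * 4)
        assert pm.leave_one_out(hs).flagged == []

    def test_dominant_outlier_flagged(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.1, 0.02, 20)
        sy = np.full(20, 0.01)
        by = 0.4 * bx + rng.normal(0, sy)
        by[3] += 25 * sy[3]
        res = pm.leave_one_out(make_hs(bx, by, sy))
        assert "rs3" in res.flagged


class TestInstrumentStrength:
    def test_direct_f(self):
        exp = pd.DataFrame([assoc("rs1", "A", "G", 0.3, 0.1, 0.01)])
        rep = pm.instrument_strength(exp)
        assert rep.f_stats.iloc[0] == pytest.approx(100.0)
        assert rep.n_strong == 1

    def test_null_effect_gives_zero(self):
        exp = pd.DataFrame([assoc("rs1", "A", "G", 0.3, 0.0, 0.01)])
        assert pm.instrument_strength(exp).f_stats.iloc[0] == 0.0

    def test_mean_f_matches_noncentral_chi_square(self):
        """Instruments tuned to E[F] = 30: mean F lands in [25, 35]."""
        rng = np.random.default_rng(9)
        means = []
        target = np.sqrt(29.0)  # E[(z + target)^2] = 1 + target^2 = 30
        for _ in range(200):
            se = np.full(40, 0.01)
            beta = se * (target + rng.standard_normal(40))
            exp = pd.DataFrame(
                [assoc(f"rs{i}", "A", "G", 0.3, beta[i], se[i]) for i in range(40)]
            )
            means.append(pm.instrument_strength(exp).mean_f)
        assert 25 <= float(np.mean(means)) <= 35
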