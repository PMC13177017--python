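"""Tests of the synthetic campaign generator: marginals, copula, profiles,
spectra and PMF fixtures."""

import numpy as np
import pytest
from scipy import stats as sps

from pmrisk import constants as C
from pmrisk import epr
from pmrisk import synthetic as syn


def _single_analyte_config(median, gsd, n_days=104, seed=1):
    return syn.GeneratorConfig(
        n_days=n_days,
        analytes={"PM2.5": syn.LognormalSpec(median, gsd)},
        rank_correlation=np.eye(1),
        congener_dirichlet={"SCCP": {"C13": 1.0}},
        seed=seed,
    )


class TestGenerateCampaign:
    def test_degenerate_gsd_collapses_to_median(self):
        cfg = _single_analyte_config(100.0, 1 + 1e-12)
        samples = syn.generate_campaign(cfg)
        vals = np.array([s.conc["PM2.5"] for s in samples])
        assert np.allclose(vals, 100.0, rtol=1e-9)

    def test_geometric_mean_tracks_configured_median(self):
        # oracle: the log of a lognormal(median m) has mean ln m, so the
        # geometric mean of 104 draws is within a few SEM of m
        cfg = _single_analyte_config(1.0e3, 1.8, seed=1)
        vals = np.array([s.conc["PM2.5"] for s in syn.generate_campaign(cfg)])
        gmean = float(np.exp(np.mean(np.log(vals))))
        assert abs(gmean - 1.0e3) / 1.0e3 < 0.15

    def test_median_convergence_at_large_n(self):
        cfg = syn.default_config(n_days=10_000, seed=3)
        frame = syn.campaign_frame(syn.generate_campaign(cfg))
        for name, spec in cfg.analytes.items():
            med = float(frame[name].median())
            assert abs(med - spec.median) / spec.median < 0.05, name

    def test_copula_preserves_marginals_ks(self):
        cfg = syn.default_config(n_days=10_000, seed=4)
        frame = syn.campaign_frame(syn.generate_campaign(cfg))
        spec = cfg.analytes["SCCP"]
        d, _ = sps.kstest(
            frame["SCCP"], "lognorm", args=(spec.sigma, 0.0, spec.median)
        )
        assert d < 0.05

    def test_spearman_targets_reached(self):
        # copula Monte Carlo oracle: the CP-EPFR rank correlation of 0.30
        # should be recovered within 0.03 at n = 1e4
        cfg = syn.default_config(n_days=10_000, seed=5)
        frame = syn.campaign_frame(syn.generate_campaign(cfg))
        r, _ = sps.spearmanr(frame["CPs"], frame["EPFR"])
        assert 0.27 <= r <= 0.33
        r_m, _ = sps.spearmanr(frame["MCCP"], frame["NO2"])
        assert abs(r_m - 0.47) < 0.04

    def test_deterministic_for_fixed_seed(self):
        a = syn.campaign_frame(syn.generate_campaign(syn.default_config(seed=9)))
        b = syn.campaign_frame(syn.generate_campaign(syn.default_config(seed=9)))
        assert a.equals(b)

    def test_meteorology_ranges(self, campaign_frame):
        assert campaign_frame["RH"].between(0, 100).all()
        assert campaign_frame["WD"].between(0, 360, inclusive="left").all()
        assert (campaign_frame["WS"] > 0).all()

    def test_non_psd_correlation_rejected_with_repair_hint(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="nearest_psd"):
            syn.GeneratorConfig(
                n_days=10,
                analytes={
                    k: syn.LognormalSpec(1.0, 1.5) for k in ("a", "b", "c")
                },
                rank_correlation=bad,
                congener_dirichlet={"SCCP": {"C13": 1.0}},
            )
        repaired = syn.nearest_psd(bad)
        assert np.linalg.eigvalsh(repaired).min() >= -1e-12
        assert np.allclose(np.diag(repaired), 1.0)


class TestCongenerProfiles:
    def test_single_cell_share_is_one(self):
        cfg = _single_analyte_config(1.0, 1.5)
        profiles = syn.generate_congener_profiles(cfg, 10)["SCCP"]
        assert all(p.shares["C13"] == pytest.approx(1.0) for p in profiles)

    def test_mean_shares_match_dirichlet_means(self):
        # Dirichlet moment oracle: E[share] = alpha / sum(alpha)
        cfg = syn.default_config(seed=7)
        profiles = syn.generate_congener_profiles(cfg, 5000)["SCCP"]
        targets = {"C13": 0.4096, "C11": 0.2541, "C12": 0.2289, "C10": 0.1074}
        for cell, target in targets.items():
            mean_share = np.mean([p.shares[cell] for p in profiles])
            assert abs(mean_share - target) < 0.01, cell

    def test_equal_concentrations_give_uniform_means(self):
        cfg = syn.GeneratorConfig(
            n_days=10,
            analytes={"PM2.5": syn.LognormalSpec(1.0, 1.5)},
            rank_correlation=np.eye(1),
            congener_dirichlet={"LCCP": {c: 5.0 for c in ("C18", "C19", "C20")}},
            seed=2,
        )
        profiles = syn.generate_congener_profiles(cfg, 4000)["LCCP"]
        for cell in ("C18", "C19", "C20"):
            assert np.mean([p.shares[cell] for p in profiles]) == pytest.approx(
                1 / 3, abs=0.01
            )

    def test_chlorine_content_near_class_means(self):
        cfg = syn.default_config(seed=8)
        out = syn.generate_congener_profiles(cfg, 2000)
        for cls, target in (("SCCP", 58.40), ("MCCP", 53.68), ("LCCP", 51.23)):
            mean = np.mean([p.chlorine_content for p in out[cls]])
            assert abs(mean - target) < 0.2

    def test_empty_cell_set_rejected(self):
        with pytest.raises(ValueError, match="empty congener"):
            syn.GeneratorConfig(
                n_days=10,
                analytes={"PM2.5": syn.LognormalSpec(1.0, 1.5)},
                rank_correlation=np.eye(1),
                congener_dirichlet={"SCCP": {}},
            )


class TestEPRSpectrumGenerator:
    def test_zero_spins_zero_noise_is_flat(self):
        spec = syn.generate_epr_spectrum(0.0, noise_sd=0.0)
        assert np.all(spec.intensity == 0.0)

    def test_line_center_at_resonance_field(self):
        # B0 = h nu / (g mu_B), evaluated with CODATA constants
        spec = syn.generate_epr_spectrum(1e12, g=2.0036, freq_GHz=9.5)
        b0 = C.PLANCK_H * 9.5e9 / (2.0036 * C.BOHR_MAGNETON) * 1e3
        assert b0 == pytest.approx(338.8, abs=0.1)
        i_zero = np.argmin(np.abs(spec.intensity[1:-1]))  # crossing near center
        fit = epr.fit_line(spec)
        assert fit.center_mT == pytest.approx(b0, abs=1e-6)

    def test_double_integral_linear_in_spins(self):
        a1 = epr.double_integral(syn.generate_epr_spectrum(1e10))
        a2 = epr.double_integral(syn.generate_epr_spectrum(2e10))
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            syn.generate_epr_spectrum(1e10, noise_sd=-1.0)

    def test_g_factor_draws_inside_observed_range(self):
        gs = syn.sample_g_factors(500, seed=3)
        assert gs.min() >= 2.0033 and gs.max() <= 2.0040


class TestPMFDataset:
    def test_zero_noise_exact_product(self):
        F, G = syn.example_factor_design(3, 9, 40, seed=0)
        pin, truth = syn.generate_pmf_dataset(F, G, 0.0, seed=1)
        assert np.allclose(pin.X, G @ F)
        assert truth["n_truncated"] == 0

    def test_residual_scaling_oracle(self):
        # with sd = K*x the standardised residuals have unit scale
        F, G = syn.example_factor_design(3, 15, 100, seed=1)
        pin, truth = syn.generate_pmf_dataset(F, G, 0.10, seed=2)
        z = np.abs(pin.X - truth["X_clean"]) / pin.U
        # E|N(0,1)| = sqrt(2/pi) ~ 0.80; allow for truncation and U from noisy X
        assert 0.6 < z.mean() < 1.2

    def test_rank_one_structure(self):
        F = np.array([[0.2, 0.3, 0.5]])
        G = np.full((20, 1), 4.0)
        pin, _ = syn.generate_pmf_dataset(F, G, 0.0, seed=0)
        assert np.linalg.matrix_rank(pin.X, tol=1e-10) == 1

    def test_truncation_recorded_not_dropped(self):
        F = np.array([[1.0, 1e-6]])
        G = np.abs(np.random.default_rng(0).normal(1.0, 0.1, size=(50, 1)))
        pin, truth = syn.generate_pmf_dataset(F, G, 0.9, seed=3)
        assert np.all(pin.X >= 0)
        assert truth["n_truncated"] == int(truth["truncated_mask"].sum())
        assert truth["n_truncated"] > 0
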