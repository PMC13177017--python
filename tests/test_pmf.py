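"""Uncertainty-weighted PMF: objective, recovery, diagnostics, matching."""

import numpy as np
import pytest

from pmrisk import pmf
from pmrisk import synthetic as syn


@pytest.fixture(scope="module")
def design():
    """Separable 5-factor ground truth shared by the recovery tests."""
    F, G = syn.example_factor_design(k=5, n_species=15, n_samples=100, seed=0)
    return F, G


class TestBuildUncertainty:
    def test_k_times_concentration(self):
        X = np.array([[100.0, 50.0]])
        U = pmf.build_uncertainty(X, {"a": 0.10, "b": 0.15}, ["a", "b"])
        assert U[0, 0] == 10.0
        assert U[0, 1] == 7.5

    def test_zero_concentration_floored(self):
        U = pmf.build_uncertainty(np.array([[0.0]]), {"a": 0.10}, ["a"])
        assert U[0, 0] > 0

    def test_missing_species_listed(self):
        with pytest.raises(KeyError, match="b"):
            pmf.build_uncertainty(np.ones((2, 2)), {"a": 0.1}, ["a", "b"])

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pmf.build_uncertainty(np.ones((1, 1)), {"a": 1.5}, ["a"])


class TestQExpected:
    def test_arithmetic(self):
        pin = pmf.PMFInput(np.ones((100, 20)), np.ones((100, 20)))
        assert pmf.q_expected(pin, 5) == 1400.0

    def test_overparameterized_rejected(self):
        pin = pmf.PMFInput(np.ones((10, 5)), np.ones((10, 5)))
        with pytest.raises(ValueError, match="over-parameterize"):
            pmf.q_expected(pin, 4)

    def test_monotone_decreasing_in_k(self):
        pin = pmf.PMFInput(np.ones((50, 12)), np.ones((50, 12)))
        qs = [pmf.q_expected(pin, k) for k in (1, 2, 3, 4)]
        assert qs == sorted(qs, reverse=True)


class TestPMFFit:
    def test_noiseless_exact_recovery(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.0, seed=1)
        res = pmf.pmf_fit(pin, k=5, n_starts=10, seed=0)
        assert res.Q < 1e-6
        _, cos, exact = pmf.match_factors(res.F, F)
        assert exact
        assert cos.min() >= 0.999

    def test_rank_one_exact(self):
        F = np.array([[0.2, 0.3, 0.5]])
        G = np.abs(np.random.default_rng(1).lognormal(0, 0.4, (20, 1)))
        pin, _ = syn.generate_pmf_dataset(F, G, 0.0, seed=0)
        res = pmf.pmf_fit(pin, k=1, n_starts=2, seed=0)
        assert np.allclose(res.G @ res.F, pin.X, rtol=1e-6, atol=1e-9)

    def test_q_near_expected_at_matched_noise(self, design):
        # residual-scaling oracle: with sd = K x and the right k,
        # Q/Q_expected is near 1
        F3, G3 = syn.example_factor_design(k=3, n_species=15, n_samples=100, seed=2)
        pin, _ = syn.generate_pmf_dataset(F3, G3, 0.10, seed=3)
        res = pmf.pmf_fit(pin, k=3, n_starts=5, seed=0)
        assert 0.5 < res.Q / res.Q_expected < 2.0

    def test_q_history_non_increasing(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.10, seed=4)
        res = pmf.pmf_fit(pin, k=5, n_starts=2, seed=0)
        hist = np.array(res.q_history)
        assert np.all(np.diff(hist) <= 0)

    def test_noiseless_solution_seed_invariant(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.0, seed=1)
        res_a = pmf.pmf_fit(pin, k=5, n_starts=5, seed=0)
        res_b = pmf.pmf_fit(pin, k=5, n_starts=5, seed=123)
        _, cos, _ = pmf.match_factors(res_a.F, res_b.F)
        assert cos.min() > 0.999

    def test_f_rows_normalized(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.10, seed=5)
        res = pmf.pmf_fit(pin, k=5, n_starts=3, seed=0)
        assert np.allclose(res.F.sum(axis=1), 1.0)
        assert np.all(res.G >= 0) and np.all(res.F >= 0)

    def test_invalid_k_rejected(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.10, seed=6)
        with pytest.raises(ValueError):
            pmf.pmf_fit(pin, k=15, n_starts=1, seed=0)

    def test_agrees_with_unweighted_nmf_oracle(self):
        # constant uncertainties reduce PMF to plain NMF; scikit-learn's
        # solver is the independent reference for the achieved fit quality
        sklearn = pytest.importorskip("sklearn.decomposition")
        F, G = syn.example_factor_design(k=3, n_species=9, n_samples=60, seed=7)
        X = G @ F
        U = np.full_like(X, X.mean())
        pin = pmf.PMFInput(X=X, U=U)
        res = pmf.pmf_fit(pin, k=3, n_starts=5, seed=0)
        nmf = sklearn.NMF(n_components=3, init="nndsvda", max_iter=2000, tol=1e-10)
        W = nmf.fit_transform(X)
        err_ref = np.linalg.norm(X - W @ nmf.components_)
        err_ours = np.linalg.norm(X - res.G @ res.F)
        assert err_ours <= err_ref + 1e-6 * np.linalg.norm(X)


class TestContributions:
    def test_single_factor_is_100_percent(self):
        F = np.array([[0.5, 0.5]])
        G = np.abs(np.random.default_rng(0).lognormal(0, 0.3, (10, 1)))
        pin, _ = syn.generate_pmf_dataset(F, G, 0.0, seed=0)
        res = pmf.pmf_fit(pin, k=1, n_starts=2, seed=0)
        contrib = pmf.contributions(res, pin)
        assert np.allclose(contrib.to_numpy(), 100.0)

    def test_orthogonal_factors_split_100_0(self):
        # two sources with disjoint tracer species: each species' mass is
        # attributed entirely to its own factor
        F = np.array([[0.6, 0.4, 0.0, 0.0], [0.0, 0.0, 0.3, 0.7]])
        rng = np.random.default_rng(1)
        G = rng.lognormal(0, 0.4, (30, 2))
        G[:5, 1] = 0.0
        G[5:10, 0] = 0.0
        pin, _ = syn.generate_pmf_dataset(F, G, 0.0, seed=0)
        res = pmf.pmf_fit(pin, k=2, n_starts=5, seed=0)
        contrib = pmf.contributions(res, pin).to_numpy()
        assert np.allclose(np.sort(contrib, axis=0)[-1], 100.0, atol=1e-3)
        assert np.allclose(np.sort(contrib, axis=0)[0], 0.0, atol=1e-3)

    def test_recovered_percentages_near_truth(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.10, seed=2)
        res = pmf.pmf_fit(pin, k=5, n_starts=10, seed=0)
        perm, _, _ = pmf.match_factors(res.F, F)
        est = pmf.contributions(res, pin).to_numpy()[list(perm)]
        per_factor = G.sum(axis=0)[:, None] * F
        truth = 100.0 * per_factor / per_factor.sum(axis=0)
        assert np.abs(est - truth).max() < 5.0

    def test_columns_sum_to_100(self, design):
        F, G = design
        pin, _ = syn.generate_pmf_dataset(F, G, 0.10, seed=8)
        res = pmf.pmf_fit(pin, k=5, n_starts=3, seed=0)
        sums = pmf.contributions(res, pin).sum(axis=0)
        assert np.allclose(sums, 100.0, atol=0.1)


class TestMatchFactors:
    def test_identity(self):
        F = np.random.default_rng(0).uniform(0.1, 1, (4, 6))
        perm, cos, exact = pmf.match_factors(F, F)
        assert perm == (0, 1, 2, 3)
        assert np.allclose(cos, 1.0)
        assert exact

    def test_row_permutation_recovered(self):
        F = np.random.default_rng(1).uniform(0.1, 1, (5, 8))
        order = [3, 0, 4, 1, 2]
        perm, cos, _ = pmf.match_factors(F[order], F)
        # F_est[perm[i]] must reproduce F_true[i]
        assert [order[p] for p in perm] == list(range(5))
        assert np.allclose(cos, 1.0)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            pmf.match_factors(np.ones((2, 3)), np.ones((3, 3)))


def test_factor_scan_reports_diagnostics():
    F, G = syn.example_factor_design(k=3, n_species=10, n_samples=50, seed=9)
    pin, _ = syn.generate_pmf_dataset(F, G, 0.10, seed=1)
    scan = pmf.factor_scan(pin, k_range=(2, 3, 4), n_starts=3, seed=0)
    assert list(scan["k"]) == [2, 3, 4]
    # Q improves (weakly) as factors are added
    assert scan["Q"].is_monotonic_decreasing
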