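"""Marker coding, GRMs, REML variance components and genomic prediction."""

import numpy as np
import pytest
from scipy.optimize import minimize

import breedsim as bs
from breedsim.errors import (DegenerateDataError, InvalidConfigurationError,
                             UndefinedReliabilityError)
from breedsim.gblup import gblup_genomic_values


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestCoding:
    def test_values_at_half_frequency(self):
        d = np.array([[2], [1], [0]])
        W, S = bs.code_markers(d, np.array([0.5]))
        assert np.allclose(W.ravel(), [1.0, 0.0, -1.0])
        assert np.allclose(S.ravel(), [-0.5, 0.5, -0.5])

    def test_fixed_marker_zero_coded(self):
        d = np.array([[2], [2], [2]])
        W, S = bs.code_markers(d, np.array([1.0]))
        assert np.all(W == 0) and np.all(S == 0)

    def test_additive_columns_centred_at_observed_frequency(self):
        # identity n_AA(2-2p) + n_Aa(1-2p) + n_aa(-2p) = 0 at observed p
        d = _rng(1).integers(0, 3, size=(60, 15))
        p = d.mean(axis=0) / 2
        W, _ = bs.code_markers(d, p)
        assert np.allclose(W.sum(axis=0), 0, atol=1e-9)

    def test_dominance_columns_centred_under_hwe(self, f2_default):
        # S centres in expectation under Hardy-Weinberg genotype ratios
        d = f2_default.dosages()
        p = d.mean(axis=0) / 2
        _, S = bs.code_markers(d, p)
        assert np.abs(S.mean(axis=0)).mean() < 0.02

    def test_invalid_dosage_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            bs.code_markers(np.array([[3]]), np.array([0.5]))


class TestGRM:
    def test_single_marker_hand_computation(self):
        d = np.array([[2], [1], [0]])
        p = np.array([0.5])
        W, S = bs.code_markers(d, p)
        Ga, Gd = bs.build_grm(W, S, p)
        # W = (1, 0, -1)^T, denominator 0.5 -> diag (2, 0, 2)
        assert np.allclose(np.diag(Ga), [2.0, 0.0, 2.0])
        assert Ga[0, 2] == pytest.approx(-2.0)

    def test_identical_genotypes_identical_rows(self):
        d = np.array([[2, 1, 0], [2, 1, 0], [0, 1, 2]])
        p = d.mean(axis=0) / 2
        W, S = bs.code_markers(d, p)
        Ga, _ = bs.build_grm(W, S, p)
        assert np.allclose(Ga[0], Ga[1])

    def test_mean_diagonal_near_one_in_f2(self, f2_default):
        d = f2_default.dosages()
        p = d.mean(axis=0) / 2
        W, S = bs.code_markers(d, p)
        Ga, Gd = bs.build_grm(W, S, p)
        assert np.diag(Ga).mean() == pytest.approx(1.0, abs=0.05)
        assert np.diag(Gd).mean() == pytest.approx(1.0, abs=0.05)

    def test_haplotype_order_irrelevant(self, two_marker_map):
        p1, p2 = bs.make_founders(two_marker_map)
        f2 = bs.make_f2(p1, p2, 50, two_marker_map, _rng(2))
        d1 = f2.dosages()
        swapped = f2.haplotypes[:, ::-1, :]
        d2 = swapped.sum(axis=1)
        assert np.array_equal(d1, d2)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(DegenerateDataError):
            bs.grm_denominators(np.array([0.0, 1.0]))


def _simulate_gblup_data(n, m, sa, sd, se, seed):
    """y = u_a + u_d + e with u ~ N(0, G sigma2) on random F2-ish dosages."""
    rng = _rng(seed)
    d = rng.integers(0, 3, size=(n, m))
    p = d.mean(axis=0) / 2
    W, S = bs.code_markers(d, p)
    Ga, Gd = bs.build_grm(W, S, p)
    jitter = 1e-8 * np.eye(n)
    la = np.linalg.cholesky(Ga + jitter)
    ld = np.linalg.cholesky(Gd + jitter)
    y = (np.sqrt(sa) * la @ rng.normal(size=n)
         + np.sqrt(sd) * ld @ rng.normal(size=n)
         + np.sqrt(se) * rng.normal(size=n))
    return y, Ga, Gd, W, S, p


def _reml_loglik_reference(y, Ga, Gd, theta):
    """Independent restricted log-likelihood via slogdet and explicit P."""
    n = len(y)
    V = theta[0] * Ga + theta[1] * Gd + theta[2] * np.eye(n)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                   + y @ P @ y)


class TestREML:
    def test_tiny_instance_matches_direct_maximization(self):
        y, Ga, Gd, *_ = _simulate_gblup_data(12, 8, 1.0, 0.5, 1.0, seed=3)
        vc = bs.reml_fit(y, Ga, Gd, method="ai", tol=1e-10)
        # independent oracle: numerical maximisation of the reference
        # restricted likelihood over log-variances, multi-start
        def neg(logth):
            return -_reml_loglik_reference(y, Ga, Gd, np.exp(logth))
        best = np.inf
        for s in ([0, 0, 0], [-2, -2, 0], [1, -3, -1]):
            r = minimize(neg, s, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 5000})
            best = min(best, r.fun)
        fitted_ll = _reml_loglik_reference(
            y, Ga, Gd, [vc.sigma2_a, vc.sigma2_d, vc.sigma2_e])
        assert fitted_ll == pytest.approx(-best, abs=1e-5)

    def test_em_loglik_monotone(self):
        y, Ga, Gd, *_ = _simulate_gblup_data(150, 60, 1.0, 0.3, 2.0, seed=4)
        vc = bs.reml_fit(y, Ga, Gd, method="em", max_iter=200)
        assert np.all(np.diff(vc.loglik_trace) >= -1e-8)

    def test_ai_and_em_reach_same_optimum(self):
        # EM creeps sublinearly near a boundary, so compare through the
        # likelihood surface rather than raw parameters
        y, Ga, Gd, *_ = _simulate_gblup_data(150, 60, 1.0, 0.5, 2.0, seed=5)
        em = bs.reml_fit(y, Ga, Gd, method="em", tol=1e-9, max_iter=5000)
        ai = bs.reml_fit(y, Ga, Gd, method="ai", tol=1e-9)
        ll_em = _reml_loglik_reference(
            y, Ga, Gd, [em.sigma2_a, em.sigma2_d, em.sigma2_e])
        ll_ai = _reml_loglik_reference(
            y, Ga, Gd, [ai.sigma2_a, ai.sigma2_d, ai.sigma2_e])
        assert ll_ai >= ll_em - 1e-6
        assert ll_em == pytest.approx(ll_ai, abs=0.05)
        assert em.sigma2_e == pytest.approx(ai.sigma2_e, rel=0.05)

    def test_variance_recovery(self):
        # heritable fraction should be recovered within Monte-Carlo bounds
        ests = []
        for seed in range(3):
            y, Ga, Gd, *_ = _simulate_gblup_data(400, 200, 3.0, 0.0, 7.0,
                                                 seed=10 + seed)
            vc = bs.reml_fit(y, Ga, Gd, method="ai")
            ests.append(vc.sigma2_a / vc.total)
        assert np.mean(ests) == pytest.approx(0.3, abs=0.1)

    def test_pure_noise_components_hit_floor(self):
        rng = _rng(6)
        y = rng.normal(size=200)
        d = rng.integers(0, 3, size=(200, 80))
        p = d.mean(axis=0) / 2
        W, S = bs.code_markers(d, p)
        Ga, Gd = bs.build_grm(W, S, p)
        vc = bs.reml_fit(y, Ga, Gd, method="ai")
        assert vc.sigma2_a < 0.1 * np.var(y)
        assert vc.sigma2_d < 0.1 * np.var(y)

    def test_zero_variance_rejected(self):
        n = 10
        with pytest.raises(DegenerateDataError):
            bs.reml_fit(np.ones(n), np.eye(n), np.eye(n))


class TestEffects:
    def test_ridge_oracle_small_instance(self):
        dosages, y = bs.make_fixture("toy_training")
        p = dosages.mean(axis=0) / 2
        W, S = bs.code_markers(dosages, p)
        vc = bs.VarianceComponents(0.4, 0.1, 1.0)
        model = bs.solve_effects(y, W, S, vc, p, solver="mme")
        # oracle: closed-form ridge solution by direct matrix inversion
        da, dd = bs.grm_denominators(p)
        lam_a, lam_d = vc.sigma2_e / (0.4 / da), vc.sigma2_e / (0.1 / dd)
        X = np.hstack([np.ones((5, 1)), W, S])
        pen = np.diag([0.0] + [lam_a] * 3 + [lam_d] * 3)
        sol = np.linalg.solve(X.T @ X + pen, X.T @ y)
        assert model.intercept == pytest.approx(sol[0], abs=1e-8)
        assert np.allclose(model.additive_effects, sol[1:4], atol=1e-8)
        assert np.allclose(model.dominance_effects, sol[4:], atol=1e-8)

    def test_covariance_route_matches_mme(self):
        dosages, y = bs.make_fixture("toy_training")
        p = dosages.mean(axis=0) / 2
        W, S = bs.code_markers(dosages, p)
        vc = bs.VarianceComponents(0.4, 0.1, 1.0)
        a = bs.solve_effects(y, W, S, vc, p, solver="mme")
        b = bs.solve_effects(y, W, S, vc, p, solver="covariance")
        assert np.allclose(a.additive_effects, b.additive_effects, atol=1e-8)
        assert np.allclose(a.dominance_effects, b.dominance_effects, atol=1e-8)

    def test_infinite_shrinkage_kills_effects(self):
        dosages, y = bs.make_fixture("toy_training")
        p = dosages.mean(axis=0) / 2
        W, S = bs.code_markers(dosages, p)
        vc = bs.VarianceComponents(1e-12, 1e-12, 1.0)
        model = bs.solve_effects(y, W, S, vc, p)
        assert np.all(np.abs(model.additive_effects) < 1e-6)
        assert np.all(np.abs(model.dominance_effects) < 1e-6)

    def test_marker_and_grm_routes_agree(self, small_map):
        p1, p2 = bs.make_founders(small_map)
        f2 = bs.make_f2(p1, p2, 150, small_map, _rng(7))
        arch = bs.TraitArchitecture.default(small_map, 0.5)
        ps = bs.simulate_phenotypes(f2, arch, 0.5, _rng(8))
        model = bs.fit(ps.phenotypes, f2.dosages(), method="ai")
        gebv_markers = model.predict(f2.dosages())
        d = f2.dosages()
        p = d.mean(axis=0) / 2
        W, S = bs.code_markers(d, p)
        Ga, Gd = bs.build_grm(W, S, p)
        gebv_grm = gblup_genomic_values(ps.phenotypes, Ga, Gd,
                                        model.variance_components)
        scale = np.max(np.abs(gebv_grm))
        assert np.allclose(gebv_markers, gebv_grm, atol=1e-6 * scale)


class TestPredict:
    def test_validation_equals_training_reproduces_gebv(self):
        dosages, y = bs.make_fixture("toy_training")
        model = bs.fit(y, dosages, method="em", max_iter=50)
        assert np.allclose(model.predict(dosages), model.predict(dosages))

    def test_monomorphic_model_predicts_zero(self):
        model = bs.MarkerModel(0.0, np.zeros(2), np.zeros(2),
                               np.array([1.0, 0.0]),
                               bs.VarianceComponents(1, 1, 1), 5)
        pred = model.predict(np.array([[2, 0], [1, 1]]))
        assert np.all(pred == 0)

    def test_single_marker_contrast_is_twice_additive_effect(self):
        freqs = np.array([0.5])
        model = bs.MarkerModel(0.0, np.array([0.7]), np.array([0.0]),
                               freqs, bs.VarianceComponents(1, 1, 1), 5)
        pred = model.predict(np.array([[2], [0]]))
        assert pred[0] - pred[1] == pytest.approx(2 * 0.7)

    def test_marker_count_mismatch_rejected(self):
        model = bs.MarkerModel(0.0, np.zeros(3), np.zeros(3),
                               np.full(3, 0.5),
                               bs.VarianceComponents(1, 1, 1), 5)
        with pytest.raises(InvalidConfigurationError):
            model.predict(np.zeros((2, 4), dtype=int))


class TestReliability:
    def test_perfect_and_sign_flipped(self):
        g = np.arange(10.0)
        assert bs.reliability(g, g) == pytest.approx(1.0)
        assert bs.reliability(-g, g) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = _rng(9)
        assert bs.reliability(rng.normal(size=5000),
                              rng.normal(size=5000)) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedReliabilityError):
            bs.reliability(np.ones(5), np.arange(5.0))
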