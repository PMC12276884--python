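"""Monte-Carlo EM solver for subject-specific dampening rates."""

import numpy as np
import pytest
from scipy import integrate

import sggm
from sggm.core import SubjectStats, build_phi
from sggm.heterogeneous import (default_tau_grid, estep, marginal_loglik,
                                posterior_grid_weights, sample_tau_posterior,
                                update_alpha)
from sggm.homogeneous import glasso_subproblem

from conftest import make_cross_sectional, random_spd


class TestPosteriorSampling:
    def test_single_row_posterior_is_truncated_prior(self, rng):
        # With one observation Phi carries no information, so the
        # posterior equals the Exponential(2) prior: mean 1/2.
        blk = sggm.SubjectBlock("a", [0.0], rng.standard_normal((1, 3)))
        omega = np.eye(3)
        draws = sample_tau_posterior(blk, omega, alpha_i=2.0, h=100_000,
                                     rng=np.random.default_rng(0))
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se + 0.01

    def test_posterior_mean_matches_quadrature(self, rng):
        blk = sggm.SubjectBlock("a", [0.0, 1.0, 2.0, 4.0],
                                rng.standard_normal((4, 3)))
        omega = random_spd(rng, 3)
        alpha = 30.0
        draws = sample_tau_posterior(blk, omega, alpha, h=10_000,
                                     rng=np.random.default_rng(1))

        def log_density(tau):
            return float(sggm.tau_posterior_logdensity(tau, blk, omega, alpha))

        ref = log_density(float(np.exp(np.mean(np.log(draws)))))

        def unnorm(tau):
            return np.exp(log_density(tau) - ref)

        lo, hi = sggm.core.TAU_MIN, sggm.core.TAU_MAX
        # guide the adaptive quadrature to the (narrow) posterior peak
        pts = np.percentile(draws, [0.1, 25, 50, 75, 99.9]).tolist()
        z, _ = integrate.quad(unnorm, lo, hi, limit=1000, points=pts)
        num, _ = integrate.quad(lambda t: t * unnorm(t), lo, hi, limit=1000,
                                points=pts)
        assert abs(draws.mean() - num / z) / (num / z) < 0.01

    def test_seeded_determinism(self, rng):
        blk = sggm.SubjectBlock("a", [0.0, 1.0], rng.standard_normal((2, 2)))
        omega = np.eye(2)
        d1 = sample_tau_posterior(blk, omega, 1.0, 50, np.random.default_rng(7))
        d2 = sample_tau_posterior(blk, omega, 1.0, 50, np.random.default_rng(7))
        assert np.array_equal(d1, d2)

    def test_weights_survive_extreme_scaling(self, rng):
        # Uniformly tiny densities must not underflow to all-zero weights.
        blk = sggm.SubjectBlock("a", [0.0, 1.0, 2.0],
                                100.0 * rng.standard_normal((3, 3)))
        omega = 100.0 * np.eye(3)
        _, w = posterior_grid_weights(SubjectStats(blk), omega, 1.0)
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)


class TestAlphaUpdate:
    def test_constant_means(self):
        assert update_alpha(np.full(7, 0.25)) == pytest.approx(4.0)

    def test_two_subject_arithmetic(self):
        assert update_alpha([0.01, 0.03]) == pytest.approx(50.0)

    def test_random_means_formula(self, rng):
        means = rng.uniform(0.01, 1.0, 5)
        assert update_alpha(means) == pytest.approx(5.0 / means.sum())

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            update_alpha([0.1, 0.0])


class TestEstep:
    def test_degenerate_grid_recovers_fixed_tau_scatter(self, rng):
        # A posterior concentrated on a single rate must hand the M-step
        # exactly the fixed-rate weighted scatter matrix.
        blocks = [sggm.SubjectBlock(f"s{i}", np.arange(3.0),
                                    rng.standard_normal((3, 2)))
                  for i in range(2)]
        stats = [SubjectStats(b) for b in blocks]
        tau_star = 0.23
        grid = np.array([tau_star, tau_star * (1 + 1e-12)])
        uniforms = [np.random.default_rng(i).random(50) for i in range(2)]
        tau_means, S0, _ = estep(stats, np.eye(2), np.array([1.0, 1.0]),
                                 uniforms, grid)
        data = sggm.LongitudinalDataset(blocks)
        assert np.allclose(tau_means, tau_star, rtol=1e-9)
        assert np.allclose(S0, sggm.sbar(tau_star, data), rtol=1e-9)

    def test_s0_symmetric(self, rng):
        blocks = [sggm.SubjectBlock(f"s{i}", np.arange(4.0),
                                    rng.standard_normal((4, 3)))
                  for i in range(3)]
        stats = [SubjectStats(b) for b in blocks]
        uniforms = [np.random.default_rng(i).random(200) for i in range(3)]
        _, S0, _ = estep(stats, random_spd(rng, 3), np.full(3, 10.0),
                         uniforms, default_tau_grid())
        assert np.allclose(S0, S0.T)


class TestMarginalLoglik:
    def test_matches_brute_force_integral(self, rng):
        # Observed-data likelihood by 1-D quadrature per subject vs the
        # package's log-sum-exp grid evaluation.
        p = 2
        blocks = [sggm.SubjectBlock("a", [0.0, 1.0], rng.standard_normal((2, p))),
                  sggm.SubjectBlock("b", [0.0, 0.5, 2.0],
                                    rng.standard_normal((3, p)))]
        stats = [SubjectStats(b) for b in blocks]
        omega = random_spd(rng, p)
        alpha = 5.0
        got = marginal_loglik(stats, omega, np.full(2, alpha))
        expected = 0.0
        lo, hi = sggm.core.TAU_MIN, sggm.core.TAU_MAX
        for blk in blocks:
            def integrand(tau, blk=blk):
                phi = build_phi(tau, blk.times)
                cov = np.kron(phi, np.linalg.inv(omega))
                y = blk.values.reshape(-1)
                sign, logdet = np.linalg.slogdet(cov)
                loglik = -0.5 * (logdet + y @ np.linalg.solve(cov, y))
                # constant (2*pi) terms omitted to match the package scale
                return np.exp(loglik) * alpha * np.exp(-alpha * tau)
            pts = np.geomspace(1e-3, 10.0, 9).tolist()
            val, _ = integrate.quad(integrand, lo, hi, limit=1000, points=pts)
            expected += np.log(val)
        assert got == pytest.approx(expected, abs=1e-4)


class TestFitHeterogeneous:
    def test_cross_sectional_reduces_to_glasso(self):
        data, _ = make_cross_sectional(p=5, n=30, seed=11)
        fit = sggm.fit_heterogeneous(data, 0.2, rng=0)
        Y = data.pooled_values()
        direct = glasso_subproblem(Y.T @ Y / Y.shape[0], 0.2)
        assert np.abs(fit.omega - direct).max() < 1e-7

    def test_bit_reproducible(self):
        from conftest import make_dataset
        data, _ = make_dataset(p=6, m=5, mean_ni=5, seed=12)
        f1 = sggm.fit_heterogeneous(data, 0.3, rng=42, h=200)
        f2 = sggm.fit_heterogeneous(data, 0.3, rng=42, h=200)
        assert np.array_equal(f1.omega, f2.omega)
        assert f1.dampening.alpha == f2.dampening.alpha

    def test_rate_recovery(self):
        # tau_i ~ Exp(1/0.018): the fitted prior mean 1/alpha-hat should
        # land within a factor of two of E[tau] = 0.018 (median over reps).
        est = []
        for seed in range(8):
            gen = np.random.default_rng(600 + seed)
            truth = sggm.generate_precision(20, 0.1, gen)
            data, _ = sggm.simulate_dataset(
                truth, m=10, mean_ni=10,
                scenario={"kind": "heterogeneous", "alpha": 1 / 0.018}, rng=gen)
            lams = sggm.selection.default_lambda_grid(data, 8, 0.05)
            fit = sggm.fit_heterogeneous(data, lams[4], rng=seed)
            est.append(1.0 / fit.dampening.alpha)
        assert 0.018 / 2 < np.median(est) < 0.018 * 2

    def test_posterior_means_track_subject_rates(self):
        gen = np.random.default_rng(77)
        truth = sggm.generate_precision(15, 0.1, gen)
        data, tr = sggm.simulate_dataset(
            truth, m=10, mean_ni=12,
            scenario={"kind": "heterogeneous", "alpha": 1 / 0.05}, rng=gen)
        lams = sggm.selection.default_lambda_grid(data, 8, 0.05)
        fit = sggm.fit_heterogeneous(data, lams[4], rng=3)
        r = np.corrcoef(np.log(fit.tau_posterior_means),
                        np.log(tr.tau_spec["tau_i"]))[0, 1]
        assert r > 0.8
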