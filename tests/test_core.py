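"""Core containers, temporal kernel and likelihood identities."""

import numpy as np
import pytest

import sggm
from sggm.core import (DataValidationError, SubjectStats, build_phi,
                       center_dataset, loglik_homogeneous,
                       phi_inverse_and_logdet, s_matrix, sbar,
                       tau_posterior_logdensity)

from conftest import random_blocks, random_spd


class TestBuildPhi:
    def test_independence_limit_is_identity(self):
        assert np.array_equal(build_phi(np.inf, [0.0, 1.0, 2.0]), np.eye(3))

    def test_single_observation(self):
        assert np.array_equal(build_phi(0.5, [3.0]), [[1.0]])

    def test_kernel_value(self):
        phi = build_phi(0.018, [0.0, 1.0])
        assert phi[0, 1] == pytest.approx(np.exp(-0.018), abs=1e-15)

    @pytest.mark.parametrize("tau", [0.01, 0.3, 5.0])
    def test_positive_definite_unit_diagonal(self, tau, rng):
        t = np.sort(rng.uniform(0, 10, 8))
        phi = build_phi(tau, t)
        assert np.allclose(np.diag(phi), 1.0)
        assert np.linalg.eigvalsh(phi).min() > 0
        assert np.all((phi > 0) & (phi <= 1))

    def test_rejects_bad_inputs(self):
        with pytest.raises(DataValidationError):
            build_phi(0.1, [0.0, np.nan])
        with pytest.raises(DataValidationError):
            build_phi(0.1, [1.0, 1.0])
        with pytest.raises(ValueError):
            build_phi(-1.0, [0.0, 1.0])


class TestPhiInverse:
    def test_two_point_closed_form(self):
        tau, dt = 0.7, 1.3
        rho = np.exp(-tau * dt)
        inv, logdet = phi_inverse_and_logdet(tau, [0.0, dt])
        expected = np.array([[1, -rho], [-rho, 1]]) / (1 - rho**2)
        assert np.allclose(inv, expected, atol=1e-12)
        assert logdet == pytest.approx(np.log(1 - rho**2), abs=1e-12)

    def test_independence(self):
        inv, logdet = phi_inverse_and_logdet(np.inf, [0.0, 1.0, 2.5])
        assert np.array_equal(inv, np.eye(3))
        assert logdet == 0.0

    def test_matches_dense_inverse(self, rng):
        for _ in range(20):
            t = np.sort(rng.uniform(0, 8, 5))
            tau = float(rng.uniform(0.05, 3.0))
            phi = build_phi(tau, t)
            inv, logdet = phi_inverse_and_logdet(tau, t)
            assert np.abs(inv - np.linalg.inv(phi)).max() < 1e-10
            assert abs(logdet - np.linalg.slogdet(phi)[1]) < 1e-10

    def test_tridiagonal_structure(self):
        inv, _ = phi_inverse_and_logdet(0.4, [0.0, 1.0, 3.0, 3.5])
        off = np.triu(inv, k=2)
        assert np.all(off == 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            phi_inverse_and_logdet(0.0, [0.0, 1.0])

    def test_logdet_increases_with_tau(self):
        # Correlations shrink toward independence, so |Phi| grows with tau.
        t = np.array([0.0, 1.0, 2.0, 4.0])
        logdets = [phi_inverse_and_logdet(tau, t)[1]
                   for tau in (0.05, 0.2, 1.0, 5.0)]
        assert np.all(np.diff(logdets) > 0)


class TestScatterMatrices:
    def test_single_row_is_outer_product(self, rng):
        y = rng.standard_normal((1, 4))
        blk = sggm.SubjectBlock("a", [0.0], y)
        assert np.allclose(s_matrix(0.3, blk), np.outer(y, y))

    def test_independence_sums_outer_products(self, rng):
        y = rng.standard_normal((3, 2))
        blk = sggm.SubjectBlock("a", [0.0, 1.0, 2.0], y)
        assert np.allclose(s_matrix(np.inf, blk), y.T @ y, atol=1e-12)

    def test_kronecker_trace_identity(self, rng):
        # tr(S_i(tau) Omega) == y^T (Phi^{-1} (x) Omega) y, the identity
        # that lets the likelihood avoid n_i*p-dimensional algebra.
        for _ in range(50):
            p, ni = int(rng.integers(2, 4)), int(rng.integers(1, 5))
            t = np.sort(rng.uniform(0, 5, ni))
            if ni > 1 and np.min(np.diff(t)) < 1e-3:
                continue
            tau = float(rng.uniform(0.05, 2.0))
            Y = rng.standard_normal((ni, p))
            omega = random_spd(rng, p)
            blk = sggm.SubjectBlock("a", t, Y)
            S = s_matrix(tau, blk)
            phi = build_phi(tau, t)
            y = Y.reshape(-1)
            quad = y @ np.kron(np.linalg.inv(phi), omega) @ y
            assert abs(np.sum(S * omega) - quad) < 1e-10 * max(1, abs(quad))

    def test_sbar_single_subject(self, rng):
        blk = sggm.SubjectBlock("a", [0.0, 1.0], rng.standard_normal((2, 3)))
        data = sggm.LongitudinalDataset([blk])
        assert np.allclose(sbar(0.2, data), s_matrix(0.2, blk) / 2)

    def test_sbar_cross_sectional_any_tau(self, rng):
        blocks = [sggm.SubjectBlock(f"s{i}", [0.0], rng.standard_normal((1, 3)))
                  for i in range(10)]
        data = sggm.LongitudinalDataset(blocks)
        Y = data.pooled_values()
        for tau in (0.01, 1.0, 100.0):
            assert np.allclose(sbar(tau, data), Y.T @ Y / 10, atol=1e-12)

    def test_sbar_brute_force(self, rng):
        blocks = random_blocks(rng, m=2, p=3)
        data = sggm.LongitudinalDataset(blocks)
        taus = [0.3, 0.8]
        expected = sum(s_matrix(tau, b) for tau, b in zip(taus, blocks))
        expected /= data.n
        assert np.allclose(sbar(taus, data), expected, atol=1e-12)


class TestLoglik:
    def test_matches_dense_gaussian_density(self, rng):
        # Constant-adjusted equality with the brute-force multivariate
        # normal log-density under the Kronecker covariance.
        for _ in range(100):
            p = int(rng.integers(2, 4))
            blocks = random_blocks(rng, m=int(rng.integers(1, 3)), p=p)
            data = sggm.LongitudinalDataset(blocks)
            omega = random_spd(rng, p)
            tau = float(rng.uniform(0.05, 2.0))
            ll = loglik_homogeneous(omega, tau, data)
            dense = 0.0
            for blk in blocks:
                cov = np.kron(build_phi(tau, blk.times), np.linalg.inv(omega))
                y = blk.values.reshape(-1)
                sign, logdet = np.linalg.slogdet(cov)
                dense += -0.5 * (logdet + y @ np.linalg.solve(cov, y))
            assert abs(ll - dense) < 1e-8 * max(1.0, abs(dense))

    def test_cross_sectional_reduction(self, rng):
        blocks = [sggm.SubjectBlock(f"s{i}", [0.0], rng.standard_normal((1, 3)))
                  for i in range(12)]
        data = sggm.LongitudinalDataset(blocks)
        omega = random_spd(rng, 3)
        S = sbar(1.0, data)
        n = data.n
        expected = 0.5 * n * (np.linalg.slogdet(omega)[1] - np.sum(S * omega))
        assert loglik_homogeneous(omega, 0.7, data) == pytest.approx(expected)

    def test_zero_data_identity_omega(self):
        blocks = [sggm.SubjectBlock("a", [0.0], np.zeros((1, 2)))]
        data = sggm.LongitudinalDataset(blocks)
        assert loglik_homogeneous(np.eye(2), 1.0, data) == pytest.approx(0.0)


class TestTauPosterior:
    def test_single_row_reduces_to_prior(self, rng):
        blk = sggm.SubjectBlock("a", [0.0], rng.standard_normal((1, 3)))
        omega = random_spd(rng, 3)
        taus = np.array([0.01, 0.1, 1.0])
        vals = tau_posterior_logdensity(taus, blk, omega, alpha_i=2.0)
        # linear in tau with slope -alpha (constant offset from the data term)
        slopes = np.diff(vals) / np.diff(taus)
        assert np.allclose(slopes, -2.0, atol=1e-10)

    def test_term_by_term_oracle(self, rng):
        blk = sggm.SubjectBlock("a", [0.0, 1.0, 2.5], rng.standard_normal((3, 2)))
        omega = random_spd(rng, 2)
        alpha = 3.0
        for tau in (0.05, 0.4, 2.0):
            phi = build_phi(tau, blk.times)
            y = blk.values.reshape(-1)
            quad = y @ np.kron(np.linalg.inv(phi), omega) @ y
            expected = (-0.5 * 2 * np.linalg.slogdet(phi)[1]
                        - 0.5 * quad - alpha * tau)
            got = float(tau_posterior_logdensity(tau, blk, omega, alpha))
            assert got == pytest.approx(expected, rel=1e-10)

    def test_finite_at_domain_floor(self, rng):
        blk = sggm.SubjectBlock("a", [0.0, 0.7, 1.9], rng.standard_normal((3, 2)))
        omega = random_spd(rng, 2)
        val = tau_posterior_logdensity(sggm.core.TAU_MIN, blk, omega, 1.0)
        assert np.isfinite(val)


class TestContainers:
    def test_block_validation(self, rng):
        with pytest.raises(DataValidationError):
            sggm.SubjectBlock("a", [0.0, 0.0], rng.standard_normal((2, 2)))
        with pytest.raises(DataValidationError):
            sggm.SubjectBlock("a", [1.0, 0.0], rng.standard_normal((2, 2)))
        with pytest.raises(DataValidationError):
            sggm.SubjectBlock("a", [0.0], [[np.nan, 1.0]])

    def test_dataset_counts_and_centering(self, rng):
        blocks = random_blocks(rng, m=3, p=2)
        data = sggm.LongitudinalDataset(blocks)
        assert data.n == sum(b.n_i for b in blocks)
        centered = center_dataset(data)
        assert np.allclose(centered.pooled_values().mean(axis=0), 0.0, atol=1e-12)

    def test_fit_edge_definition(self):
        omega = np.array([[1.0, 0.0, 0.3], [0.0, 1.0, 1e-12], [0.3, 1e-12, 1.0]])
        fit = sggm.SGGMFit(omega=omega,
                           dampening=sggm.DampeningModel("homogeneous", tau=1.0),
                           lam=0.1, loglik=0.0, loglik_penalized=0.0,
                           iterations=1, converged=True)
        assert fit.n_edges == 1
        adj = fit.adjacency()
        assert adj[0, 2] == 1 and adj[1, 2] == 0


# Property-based checks of the temporal kernel over arbitrary grids.
try:
    from hypothesis import given, settings, strategies as st

    @st.composite
    def _tau_and_times(draw):
        tau = draw(st.floats(min_value=1e-3, max_value=50.0))
        n = draw(st.integers(min_value=2, max_value=6))
        gaps = draw(st.lists(st.floats(min_value=0.05, max_value=10.0),
                             min_size=n - 1, max_size=n - 1))
        return tau, np.concatenate([[0.0], np.cumsum(gaps)])

    class TestKernelProperties:
        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(_tau_and_times())
        def test_phi_pd_and_inverse_identity(self, case):
            tau, times = case
            phi = build_phi(tau, times)
            assert np.linalg.eigvalsh(phi).min() > 0
            inv, logdet = phi_inverse_and_logdet(tau, times)
            assert np.allclose(inv @ phi, np.eye(len(times)), atol=1e-7)
            assert logdet == pytest.approx(np.linalg.slogdet(phi)[1], abs=1e-8)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
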