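"""Homogeneous longitudinal graphical lasso.

All subjects share a single dampening rate ``tau``.  The penalized
negative log-likelihood

``-2 l(Omega, tau | y) + n * lam * |Omega|_1``

is minimized by block coordinate descent: for fixed ``tau`` the ``Omega``
subproblem is an ordinary graphical lasso on the weighted scatter matrix
``S̄(tau)``; for fixed ``Omega`` the ``tau`` subproblem is a smooth 1-D
likelihood maximization, solved by bounded Brent search on ``log tau``
(any maximizer of the 1-D objective serves; Brent avoids the second
derivatives a Newton step would need near the domain boundary).
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .core import (
    TAU_MAX,
    TAU_MIN,
    DampeningModel,
    LongitudinalDataset,
    SGGMFit,
    SubjectStats,
    loglik_homogeneous,
    sbar,
)

__all__ = ["glasso_subproblem", "optimize_tau", "fit_homogeneous", "penalty_value"]


def penalty_value(omega: np.ndarray, lam: float, penalize_diagonal: bool = False) -> float:
    """``lam * |Omega|_1`` with or without the diagonal in the L1 norm."""
    total = np.abs(omega).sum()
    if not penalize_diagonal:
        total -= np.abs(np.diag(omega)).sum()
    return lam * total


def _soft_threshold_off(M: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(M) * np.maximum(np.abs(M) - t, 0.0)
    np.fill_diagonal(out, np.diag(M))
    return out


def _gista(S: np.ndarray, lam: float, tol: float = 1e-6, max_iter: int = 3000,
           omega_init=None) -> np.ndarray:
    """Graphical lasso by accelerated proximal gradient (FISTA) with
    backtracking and adaptive restart.

    Slower than coordinate descent but unconditionally stable, which
    matters when ``S`` is nearly singular (pooled rows of strongly
    autocorrelated subjects have effective rank far below ``p``).  Only
    off-diagonal entries are penalized; callers wanting a penalized
    diagonal pass ``S + lam I``.
    """
    def l1_off(om):
        return np.abs(om).sum() - np.abs(np.diag(om)).sum()

    def smooth_obj(om):
        try:
            chol = np.linalg.cholesky(om)
        except np.linalg.LinAlgError:
            return np.inf
        return -2.0 * np.log(np.diag(chol)).sum() + float(np.sum(S * om))

    from scipy.linalg import solve_triangular

    def factor(om):
        """(cholesky, logdet) or (None, inf) when not PD."""
        try:
            chol = np.linalg.cholesky(om)
        except np.linalg.LinAlgError:
            return None, np.inf
        return chol, 2.0 * np.log(np.diag(chol)).sum()

    omega = None
    if omega_init is not None:
        chol0, _ = factor(np.asarray(omega_init, dtype=float))
        if chol0 is not None:
            omega = np.asarray(omega_init, dtype=float).copy()
    if omega is None:
        omega = np.diag(1.0 / (np.diag(S) + lam))
    theta = omega.copy()
    t_k = 1.0
    step = 1.0 / max(np.diag(S).max(), 1.0) ** 2
    chol, logdet = factor(omega)
    full_obj = -logdet + float(np.sum(S * omega)) + lam * l1_off(omega)
    prev_theta = prev_grad = None
    eyep = np.eye(S.shape[0])
    for _ in range(max_iter):
        chol, logdet_theta = factor(theta)
        if chol is None:
            theta, t_k = omega.copy(), 1.0
            chol, logdet_theta = factor(theta)
        inv_chol = solve_triangular(chol, eyep, lower=True)
        grad = S - inv_chol.T @ inv_chol
        f_theta = -logdet_theta + float(np.sum(S * theta))
        # Barzilai-Borwein guess for the next step length.
        if prev_theta is not None:
            s_vec = theta - prev_theta
            y_vec = grad - prev_grad
            denom = float(np.sum(s_vec * y_vec))
            if denom > 0:
                step = max(min(float(np.sum(s_vec * s_vec)) / denom, 1e4), 1e-10)
        prev_theta, prev_grad = theta, grad
        while True:
            cand = _soft_threshold_off(theta - step * grad, step * lam)
            chol_c, logdet_c = factor(cand)
            if chol_c is not None:
                f_cand = -logdet_c + float(np.sum(S * cand))
                diff = cand - theta
                majorant = (f_theta + float(np.sum(grad * diff))
                            + float(np.sum(diff * diff)) / (2 * step))
                if f_cand <= majorant + 1e-10 * abs(majorant):
                    break
            step *= 0.5
        cand_obj = f_cand + lam * l1_off(cand)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        theta_next = cand + ((t_k - 1.0) / t_next) * (cand - omega)
        if cand_obj > full_obj:  # adaptive restart on non-monotone step
            t_next, theta_next = 1.0, cand.copy()
        delta = np.max(np.abs(cand - omega))
        omega, full_obj, theta, t_k = cand, cand_obj, theta_next, t_next
        if delta < tol:
            break
    return omega


def _fht_glasso(S: np.ndarray, lam: float, tol: float = 1e-4,
                max_iter: int = 200) -> np.ndarray:
    """Block coordinate descent graphical lasso (the classical algorithm
    behind the reference R implementation).

    Cycles over nodes, solving each column's lasso subproblem on the
    current working covariance with scikit-learn's Gram coordinate-descent
    core, then assembles the precision from the regression coefficients.
    Markedly more robust than the all-at-once coordinate descent on
    near-singular inputs.  Off-diagonal penalty only.
    """
    from sklearn.linear_model import _cd_fast as cd_fast
    from sklearn.utils import check_random_state

    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    idx = np.arange(p)
    rng = check_random_state(0)
    scale = max(np.abs(np.diag(S)).max(), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            W_old = W.copy()
            for j in range(p):
                notj = idx != j
                W11 = np.ascontiguousarray(W[np.ix_(notj, notj)])
                s12 = np.ascontiguousarray(S[notj, j])
                w = B[notj, j].copy()
                w, _, _, _ = cd_fast.enet_coordinate_descent_gram(
                    w, lam, 0.0, W11, s12, s12, 100, 1e-6, rng, False, False)
                B[notj, j] = w
                w12 = W11 @ w
                W[notj, j] = w12
                W[j, notj] = w12
            if np.abs(W - W_old).max() < tol * scale:
                break
        else:
            warnings.warn("block-coordinate graphical lasso did not converge")
    omega = np.zeros((p, p))
    for j in range(p):
        notj = idx != j
        denom = W[j, j] - float(W[notj, j] @ B[notj, j])
        omega[j, j] = 1.0 / denom
        omega[notj, j] = -B[notj, j] / denom
    omega = 0.5 * (omega + omega.T)
    zero = ~((B != 0) | (B.T != 0)) & ~np.eye(p, dtype=bool)
    omega[zero] = 0.0
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        # under-converged sweeps can leave an indefinite assembly; the
        # proximal-gradient solver is slower but guarantees PD iterates
        omega = _gista(S, lam, omega_init=None)
    return omega


def glasso_subproblem(S: np.ndarray, lam: float, *, penalize_diagonal: bool = False,
                      tol: float = 1e-3, max_iter: int = 100,
                      omega_init=None) -> np.ndarray:
    """L1-penalized precision estimate ``argmin -log|Omega| + tr(S Omega) + lam |Omega|_1``.

    By default only off-diagonal entries are penalized, which keeps the
    precision diagonal on the scale of ``1/diag(S)`` — important here
    because the dampening-rate update reads that scale.  With
    ``penalize_diagonal=True`` the optimum has positive diagonal entries,
    making the problem equivalent to an off-diagonal-only graphical lasso
    on ``S + lam I``; either way the subproblem is handed to scikit-learn's
    coordinate-descent solver.

    Non-convergence is signalled with a warning and the best iterate is
    returned.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    target = S + lam * np.eye(S.shape[0]) if penalize_diagonal else S
    eye = np.eye(S.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        omega = None
        try:
            _, omega = _sk_graphical_lasso(target, alpha=lam, tol=tol, max_iter=max_iter)
            np.linalg.cholesky(0.5 * (omega + omega.T))
        except (FloatingPointError, np.linalg.LinAlgError):
            # sklearn's all-at-once coordinate descent can fail — or return
            # an indefinite matrix without raising — on (near-)singular
            # inputs, e.g. a pooled covariance whose effective rank is far
            # below p.  Fall back to the classical block-coordinate
            # algorithm, then to proximal gradient.
            try:
                omega = _fht_glasso(target, lam)
            except ImportError:  # pragma: no cover - private API moved
                omega = _gista(target, lam, omega_init=omega_init)
    return 0.5 * (omega + omega.T)


def optimize_tau(omega: np.ndarray, data: LongitudinalDataset, tau_init: float,
                 stats: Optional[list[SubjectStats]] = None,
                 bounds: tuple[float, float] = (TAU_MIN, TAU_MAX)) -> float:
    """Maximize the homogeneous log-likelihood over ``tau`` for fixed ``Omega``.

    Returns ``tau_init`` with a warning when no subject has two or more
    observations (the likelihood is then flat in ``tau``).
    """
    if stats is None:
        stats = [SubjectStats(b) for b in data.subjects]
    if not any(s.n_i >= 2 for s in stats):
        warnings.warn("tau is unidentifiable: every subject has a single "
                      "observation; returning tau_init")
        return float(tau_init)
    p = stats[0].p
    qr = [s.trace_terms(omega) for s in stats]

    def neg_profile(log_tau: float) -> float:
        tau = math.exp(log_tau)
        total = 0.0
        for s, (q, r) in zip(stats, qr):
            from .core import phi_factors
            a, b, ld = phi_factors(tau, s.gaps)
            total += p * float(ld) + float(a @ q) + 2.0 * (float(b @ r) if r.size else 0.0)
        return total

    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    res = minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    tau_hat = float(math.exp(res.x))
    # Never move downhill from the starting point.
    t0 = float(np.clip(tau_init, *bounds))
    if neg_profile(math.log(t0)) < res.fun:
        tau_hat = t0
    return tau_hat


def fit_homogeneous(data: LongitudinalDataset, lam: float, *, tau_init: float = 0.1,
                    tol: float = 1e-3, max_outer: int = 50,
                    penalize_diagonal: bool = False, glasso_tol: float = 1e-3,
                    glasso_max_iter: int = 100,
                    stop_rule: str = "ebic", patience: int = 3) -> SGGMFit:
    """Fit the homogeneous SGGM at a single penalty ``lam``.

    Alternates the graphical-lasso update of ``Omega`` on ``S̄(tau)`` with
    the 1-D likelihood maximization over ``tau``.  With one observation per
    subject the temporal kernel carries no information and the fit reduces
    exactly to a plain graphical lasso on the empirical second-moment
    matrix.

    Like its latent-rate siblings, this model's penalized likelihood is
    unbounded along the direction where ``tau`` shrinks toward zero while
    ``Omega`` rescales, so iterating to stationarity drifts toward a
    degenerate dense fit.  The default ``stop_rule="ebic"`` tracks the
    profile-likelihood EBIC of each iterate and returns the best one
    (early-stopping regularization); ``stop_rule="tolerance"`` runs until
    the changes in ``tau`` and ``Omega`` fall below ``tol``.
    """
    if stop_rule not in ("ebic", "tolerance"):
        raise ValueError("stop_rule must be 'ebic' or 'tolerance'")
    stats = [SubjectStats(b) for b in data.subjects]
    n, p = sum(s.n_i for s in stats), data.p
    identifiable = any(s.n_i >= 2 for s in stats)

    tau0 = float(tau_init)
    S = sbar(tau0, stats)
    omega0 = np.diag(1.0 / (np.diag(S) + lam))
    converged = False
    iterations = 0
    best = None
    since_best = 0
    with warnings.catch_warnings():
        if not identifiable:
            warnings.simplefilter("ignore")  # single flat-likelihood warning
        for iterations in range(1, max_outer + 1):
            omega = glasso_subproblem(sbar(tau0, stats), lam,
                                      penalize_diagonal=penalize_diagonal,
                                      tol=glasso_tol, max_iter=glasso_max_iter,
                                      omega_init=omega0)
            tau = optimize_tau(omega, data, tau0, stats=stats) if identifiable else tau0
            if stop_rule == "ebic":
                adj = np.abs(omega) > 1e-8
                E = int(adj[np.triu_indices(p, k=1)].sum())
                crit = (-2.0 * loglik_homogeneous(omega, tau, data, stats=stats)
                        + E * (np.log(n) + np.log(p) / 2.0))
                if best is None or crit < best[0]:
                    best = (crit, tau, omega, iterations)
                    since_best = 0
                else:
                    since_best += 1
            tol_met = (abs(tau - tau0) < tol
                       and np.max(np.abs(omega - omega0)) < tol)
            tau0, omega0 = tau, omega
            if tol_met:
                converged = True
                break
            if stop_rule == "ebic" and since_best >= patience:
                converged = True
                break
    if stop_rule == "ebic" and best is not None:
        _, tau0, omega0, iterations = best
    if not identifiable:
        converged = True

    ll = loglik_homogeneous(omega0, tau0, data, stats=stats)
    pen = -2.0 * ll + n * penalty_value(omega0, lam, penalize_diagonal)
    return SGGMFit(
        omega=omega0,
        dampening=DampeningModel(kind="homogeneous", tau=tau0),
        lam=float(lam),
        loglik=float(ll),
        loglik_penalized=float(pen),
        iterations=iterations,
        converged=converged,
    )
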