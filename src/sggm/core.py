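"""Core data containers and likelihood computations for the stationary
Gaussian graphical model (SGGM).

The SGGM describes irregularly spaced longitudinal observations of a
``p``-taxon community.  Rows ``y_{i,t}`` (subject ``i``, time ``t``) are
jointly Gaussian with mean zero and a separable covariance: observations
from subject ``i`` stacked into a single vector have covariance
``Phi_i (tau_i) ⊗ Omega^{-1}``, where ``Omega`` is the shared precision
matrix (whose off-diagonal support is the interaction network) and
``Phi_i`` is an exponential-decay temporal correlation matrix with entries
``exp(-tau_i |t_j - t_k|)``.  Larger dampening rates ``tau`` mean faster
decay toward temporal independence; ``tau = +inf`` recovers the
independent-rows model used by cross-sectional pipelines such as
SPIEC-EASI.

Everything a solver needs — the temporal kernel, its tridiagonal inverse,
the per-subject weighted scatter matrices ``S_i(tau)``, the pooled matrix
``S̄(tau)`` and the profile log-likelihood — lives here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "TAU_MIN",
    "TAU_MAX",
    "EDGE_TOL",
    "SubjectBlock",
    "LongitudinalDataset",
    "DampeningModel",
    "SGGMFit",
    "build_phi",
    "phi_inverse_and_logdet",
    "phi_factors",
    "s_matrix",
    "sbar",
    "loglik_homogeneous",
    "tau_posterior_logdensity",
    "SubjectStats",
    "center_dataset",
]

# Numerically safe dampening-rate domain.  tau -> 0 drives Phi toward the
# singular all-ones matrix; tau beyond ~1e4 is indistinguishable from
# independence at any realistic time spacing.
TAU_MIN = 1e-4
TAU_MAX = 1e4

#: Off-diagonal entries of a fitted precision matrix larger than this (in
#: absolute value) count as edges.  Graphical-lasso solutions are exactly
#: sparse only up to solver tolerance.
EDGE_TOL = 1e-8


class DataValidationError(ValueError):
    """Raised when an input table violates the model's data contract."""


@dataclass
class SubjectBlock:
    """All observations from one subject.

    Parameters
    ----------
    subject_id
        Label identifying the subject.
    times
        Strictly increasing observation times (arbitrary but consistent
        units).
    values
        ``(n_i, p)`` matrix of transformed abundances, one row per time.
    covariates
        Optional covariate vector ``x_i`` (leading 1 for the intercept)
        used by the covariate-adjusted model.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    covariates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1:
            raise DataValidationError("times must be a 1-D vector")
        if not np.all(np.isfinite(self.times)):
            raise DataValidationError(
                f"subject {self.subject_id!r}: non-finite observation times"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError(
                f"subject {self.subject_id!r}: non-finite or missing abundance values"
            )
        if self.values.shape[0] != self.times.size:
            raise DataValidationError(
                f"subject {self.subject_id!r}: {self.times.size} times but "
                f"{self.values.shape[0]} value rows"
            )
        if self.times.size == 0:
            raise DataValidationError(f"subject {self.subject_id!r}: no observations")
        diffs = np.diff(self.times)
        if np.any(diffs == 0):
            raise DataValidationError(
                f"subject {self.subject_id!r}: duplicate observation times"
            )
        if np.any(diffs < 0):
            raise DataValidationError(
                f"subject {self.subject_id!r}: times must be sorted ascending"
            )
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if not np.all(np.isfinite(self.covariates)):
                raise DataValidationError(
                    f"subject {self.subject_id!r}: non-finite covariates"
                )

    @property
    def n_i(self) -> int:
        return self.times.size


@dataclass
class LongitudinalDataset:
    """A collection of per-subject observation blocks sharing ``p`` taxa."""

    subjects: list[SubjectBlock]
    taxon_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise DataValidationError("dataset has no subjects")
        p = self.subjects[0].values.shape[1]
        for blk in self.subjects:
            if blk.values.shape[1] != p:
                raise DataValidationError(
                    f"subject {blk.subject_id!r} has {blk.values.shape[1]} taxa, "
                    f"expected {p}"
                )
        if not self.taxon_names:
            self.taxon_names = [f"taxon_{j}" for j in range(p)]
        if len(self.taxon_names) != p:
            raise DataValidationError("taxon_names length does not match data")

    @property
    def p(self) -> int:
        return self.subjects[0].values.shape[1]

    @property
    def m(self) -> int:
        return len(self.subjects)

    @property
    def n(self) -> int:
        """Total number of observation rows across all subjects."""
        return sum(blk.n_i for blk in self.subjects)

    def pooled_values(self) -> np.ndarray:
        """All rows stacked into an ``(n, p)`` matrix (subject order)."""
        return np.vstack([blk.values for blk in self.subjects])

    def tau_identifiable(self) -> bool:
        """Dampening rates are informed only by subjects with >= 2 rows."""
        return any(blk.n_i >= 2 for blk in self.subjects)


def center_dataset(data: LongitudinalDataset) -> LongitudinalDataset:
    """Center each taxon to mean zero across all rows pooled.

    The model assumes a single global mean vector, so centering uses the
    grand mean per taxon, not per-subject means.
    """
    mu = data.pooled_values().mean(axis=0)
    subjects = [
        SubjectBlock(blk.subject_id, blk.times.copy(), blk.values - mu,
                     None if blk.covariates is None else blk.covariates.copy())
        for blk in data.subjects
    ]
    return LongitudinalDataset(subjects, list(data.taxon_names))


@dataclass
class DampeningModel:
    """Parametrization of the temporal-correlation decay.

    ``kind`` is one of ``homogeneous`` (single shared rate ``tau``),
    ``heterogeneous`` (subject rates ``tau_i ~ Exponential(alpha)``) or
    ``covariate`` (rates ``tau_i ~ Exponential(exp(alpha @ x_i))``).
    ``exponent_p`` is the exponent of ``|dt|`` in the kernel; only the
    working choice 1 (exponential / Markov kernel) is exercised by the
    solvers.
    """

    kind: Literal["homogeneous", "heterogeneous", "covariate"]
    tau: Optional[float] = None
    alpha: Optional[np.ndarray | float] = None
    exponent_p: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "homogeneous" and self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")

    def to_dict(self) -> dict:
        alpha = self.alpha
        if isinstance(alpha, np.ndarray):
            alpha = alpha.tolist()
        return {"kind": self.kind, "tau": self.tau, "alpha": alpha,
                "exponent_p": self.exponent_p}


@dataclass
class SGGMFit:
    """Result of one penalized SGGM fit at a fixed penalty ``lam``."""

    omega: np.ndarray
    dampening: DampeningModel
    lam: float
    loglik: float
    loglik_penalized: float
    iterations: int
    converged: bool
    tau_posterior_means: Optional[np.ndarray] = None
    #: 'exact' for the homogeneous profile likelihood, 'surrogate' for the
    #: Q-function value reported by the latent-rate (EM) models.
    loglik_kind: str = "exact"

    def adjacency(self, threshold: float = EDGE_TOL) -> np.ndarray:
        """Binary edge matrix: off-diagonals of ``omega`` above threshold."""
        adj = (np.abs(self.omega) > threshold).astype(int)
        np.fill_diagonal(adj, 0)
        return adj

    @property
    def n_edges(self) -> int:
        adj = self.adjacency()
        return int(adj[np.triu_indices_from(adj, k=1)].sum())

    def to_dict(self) -> dict:
        return {
            "omega": self.omega.tolist(),
            "dampening": self.dampening.to_dict(),
            "lam": self.lam,
            "loglik": self.loglik,
            "loglik_penalized": self.loglik_penalized,
            "loglik_kind": self.loglik_kind,
            "iterations": self.iterations,
            "converged": self.converged,
            "tau_posterior_means": None if self.tau_posterior_means is None
            else np.asarray(self.tau_posterior_means).tolist(),
            "n_edges": self.n_edges,
        }


# ---------------------------------------------------------------------------
# Temporal kernel


def build_phi(tau: float, times: Sequence[float], exponent_p: float = 1.0) -> np.ndarray:
    """Temporal correlation matrix ``Phi[j,k] = exp(-tau |t_j - t_k|^p)``.

    ``tau = +inf`` is accepted and yields the identity (independence).
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DataValidationError("non-finite observation times")
    if np.any(np.diff(t) <= 0):
        raise DataValidationError("times must be strictly increasing")
    if not tau > 0:
        raise ValueError("tau must be positive")
    if np.isinf(tau):
        return np.eye(t.size)
    with np.errstate(over="ignore"):
        return np.exp(-tau * np.abs(t[:, None] - t[None, :]) ** exponent_p)


def phi_factors(tau, gaps: np.ndarray):
    """Tridiagonal factors of ``Phi(tau)^{-1}`` for the exponential kernel.

    For exponent 1 the process is Markov on the (irregular) time grid, so
    the inverse correlation matrix is tridiagonal with entries determined by
    the lag-one correlations ``rho_k = exp(-tau * gap_k)``:

    * diagonal ``a``: ``a_1 = 1/(1-rho_1^2)``, ``a_n = 1/(1-rho_{n-1}^2)``,
      interior ``a_k = 1/(1-rho_{k-1}^2) + 1/(1-rho_k^2) - 1``;
    * off-diagonal ``b_k = -rho_k / (1-rho_k^2)``;
    * ``log|Phi| = sum_k log(1 - rho_k^2)``.

    ``tau`` may be a scalar or an array; the factors broadcast over its
    leading dimensions, giving shapes ``(..., n)``, ``(..., n-1)`` and
    ``(...,)`` for ``a``, ``b`` and ``logdet``.
    """
    tau = np.asarray(tau, dtype=float)
    n = gaps.size + 1
    shape = tau.shape
    if n == 1:
        a = np.ones(shape + (1,))
        b = np.zeros(shape + (0,))
        logdet = np.zeros(shape)
        return a, b, logdet
    with np.errstate(over="ignore", under="ignore"):
        rho = np.exp(-tau[..., None] * gaps)
    r2 = rho * rho
    inv1m = 1.0 / (1.0 - r2)
    a = np.ones(shape + (n,))
    a[..., 0] = inv1m[..., 0]
    a[..., -1] = inv1m[..., -1]
    if n > 2:
        a[..., 1:-1] = inv1m[..., :-1] + inv1m[..., 1:] - 1.0
    b = -rho * inv1m
    logdet = np.log1p(-r2).sum(axis=-1)
    return a, b, logdet


def phi_inverse_and_logdet(tau: float, times: Sequence[float]):
    """``(Phi(tau)^{-1}, log|Phi(tau)|)`` via the tridiagonal closed form."""
    t = np.asarray(times, dtype=float)
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not np.all(np.isfinite(t)):
        raise DataValidationError("non-finite observation times")
    if np.isinf(tau):
        return np.eye(t.size), 0.0
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise DataValidationError("times must be strictly increasing")
    a, b, logdet = phi_factors(float(tau), gaps)
    n = t.size
    inv = np.zeros((n, n))
    inv[np.arange(n), np.arange(n)] = a
    if n > 1:
        idx = np.arange(n - 1)
        inv[idx, idx + 1] = b
        inv[idx + 1, idx] = b
    return inv, float(logdet)


# ---------------------------------------------------------------------------
# Per-subject sufficient statistics


class SubjectStats:
    """Precomputed quadratic forms for one subject.

    The weighted scatter matrix ``S_i(tau) = Y^T Phi^{-1}(tau) Y`` is a
    linear combination of fixed ``p x p`` blocks with tau-dependent scalar
    coefficients (the tridiagonal factors), which makes both its assembly
    and the trace ``tr(S_i(tau) Omega)`` cheap to evaluate for many tau
    values at once.
    """

    def __init__(self, block: SubjectBlock):
        self.block = block
        Y = block.values
        self.gaps = np.diff(block.times)
        self.n_i, self.p = Y.shape
        # A_k = y_k y_k^T ; B_k = y_k y_{k+1}^T + y_{k+1} y_k^T
        self.A = Y[:, :, None] * Y[:, None, :]
        if self.n_i > 1:
            cross = Y[:-1, :, None] * Y[1:, None, :]
            self.B = cross + np.swapaxes(cross, 1, 2)
        else:
            self.B = np.zeros((0, self.p, self.p))

    def s_matrix_from_factors(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        S = np.tensordot(a, self.A, axes=(0, 0))
        if b.size:
            S += np.tensordot(b, self.B, axes=(0, 0))
        return S

    def s_matrix(self, tau: float) -> np.ndarray:
        a, b, _ = phi_factors(float(tau), self.gaps)
        return self.s_matrix_from_factors(a, b)

    def trace_terms(self, omega: np.ndarray):
        """``(q, r)`` with ``q_k = y_k^T Omega y_k`` and
        ``r_k = y_k^T Omega y_{k+1}``, so that
        ``tr(S_i(tau) Omega) = a(tau) . q + 2 b(tau) . r``."""
        Y = self.block.values
        W = Y @ omega
        q = np.einsum("ij,ij->i", W, Y)
        r = np.einsum("ij,ij->i", W[:-1], Y[1:]) if self.n_i > 1 else np.zeros(0)
        return q, r

    def trace_s_omega(self, tau, omega: np.ndarray):
        """``tr(S_i(tau) Omega)``, vectorized over an array of tau values."""
        q, r = self.trace_terms(omega)
        a, b, logdet = phi_factors(tau, self.gaps)
        tr = np.tensordot(a, q, axes=(-1, 0)) + 2.0 * (
            np.tensordot(b, r, axes=(-1, 0)) if r.size else 0.0
        )
        return tr, logdet


def _as_stats(block) -> SubjectStats:
    return block if isinstance(block, SubjectStats) else SubjectStats(block)


def s_matrix(tau: float, block: SubjectBlock | SubjectStats) -> np.ndarray:
    """Weighted scatter matrix ``S_i(tau) = sum_{jk} phi^{-}_{ijk} y_k y_j^T``.

    Satisfies ``tr(S_i(tau) Omega) = y_i^T (Phi_i^{-1} ⊗ Omega) y_i`` for the
    stacked observation vector ``y_i`` of the subject.
    """
    if np.isinf(tau):
        stats = _as_stats(block)
        return np.tensordot(np.ones(stats.n_i), stats.A, axes=(0, 0))
    return _as_stats(block).s_matrix(tau)


def sbar(tau, data: LongitudinalDataset | list[SubjectStats]) -> np.ndarray:
    """Pooled matrix ``S̄ = (1/n) sum_i S_i(tau_i)``.

    ``tau`` may be a scalar (shared rate) or a length-``m`` vector of
    per-subject rates.
    """
    stats = [_as_stats(b) for b in (data.subjects if isinstance(data, LongitudinalDataset) else data)]
    m = len(stats)
    taus = np.broadcast_to(np.asarray(tau, dtype=float), (m,))
    n = sum(s.n_i for s in stats)
    S = np.zeros((stats[0].p, stats[0].p))
    for s, t in zip(stats, taus):
        S += s_matrix(t, s)
    return S / n


def loglik_homogeneous(omega: np.ndarray, tau: float, data: LongitudinalDataset,
                       stats: Optional[list[SubjectStats]] = None) -> float:
    """Profile log-likelihood of the homogeneous SGGM (up to the Gaussian
    constant ``-(np/2) log 2π``):

    ``l = -1/2 [ sum_i p log|Phi_i(tau)| - n log|Omega| + n tr(S̄(tau) Omega) ]``
    """
    if stats is None:
        stats = [SubjectStats(b) for b in data.subjects]
    p = stats[0].p
    n = sum(s.n_i for s in stats)
    sign, logdet_omega = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("omega must be positive definite")
    total = 0.0
    for s in stats:
        tr, ld = s.trace_s_omega(float(tau), omega)
        total += p * float(ld) + float(tr)
    return -0.5 * (total - n * logdet_omega)


def tau_posterior_logdensity(tau, block: SubjectBlock | SubjectStats,
                             omega: np.ndarray, alpha_i: float):
    """Unnormalized log posterior of a subject's dampening rate.

    ``log g(tau | y_i) = -(p/2) log|Phi_i(tau)| - tr(S_i(tau) Omega)/2
    - alpha_i tau + const`` — the Gaussian likelihood of the subject's block
    times an Exponential(``alpha_i``) prior.  Vectorized over ``tau``.
    """
    if not alpha_i > 0:
        raise ValueError("alpha_i must be positive")
    stats = _as_stats(block)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    tr, logdet = stats.trace_s_omega(tau, omega)
    return -0.5 * stats.p * logdet - 0.5 * tr - alpha_i * tau
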