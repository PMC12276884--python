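"""Network-recovery evaluation: TPR/FPR, connection probabilities across
solution paths, ROC/AUC, and the cross-sectional comparison baselines.

The headline comparison treats each inference procedure as a scorer of
node pairs: for every replicate a solution path is computed and the
within-path proportion of networks containing an edge gives that pair's
connection probability; probabilities are averaged across replicates and
swept over thresholds to produce the ROC curve.  The baselines — plain
graphical lasso and per-node lasso neighborhood selection — pool all rows
and ignore the longitudinal correlation entirely, exactly the procedures a
cross-sectional pipeline would apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_curve

from .core import LongitudinalDataset, SGGMFit, DampeningModel
from .homogeneous import glasso_subproblem, penalty_value
from .selection import SolutionPath

__all__ = [
    "tpr_fpr",
    "connection_probabilities",
    "roc_auc",
    "baseline_glasso",
    "baseline_neighborhood",
    "NeighborhoodPath",
]


def _upper(a: np.ndarray) -> np.ndarray:
    return np.asarray(a)[np.triu_indices(a.shape[0], k=1)]


def tpr_fpr(est_adjacency: np.ndarray, true_adjacency: np.ndarray) -> tuple[float, float]:
    """True- and false-positive edge rates over undirected pairs.

    ``TPR = TP / P`` over true edges and ``FPR = FP / N`` over true
    non-edges; diagonals are ignored and each pair counts once.
    """
    est = _upper(est_adjacency) != 0
    true = _upper(true_adjacency) != 0
    if est.size != true.size:
        raise ValueError("adjacency matrices differ in size")
    P = int(true.sum())
    N = true.size - P
    if P == 0:
        raise ValueError("true network has no edges; TPR undefined")
    tp = int((est & true).sum())
    fp = int((est & ~true).sum())
    return tp / P, fp / N if N else 0.0


def _stack(path) -> np.ndarray:
    if hasattr(path, "adjacency_stack"):
        return path.adjacency_stack()
    return np.stack([np.asarray(a) for a in path])


def connection_probabilities(paths) -> np.ndarray:
    """Edge frequencies along paths, averaged across replicates.

    ``paths`` is an iterable of replicates, each a solution path (or plain
    list of adjacency matrices).  The within-path proportion of networks
    containing each edge is computed first; those per-replicate proportions
    are then averaged, so replicates with paths of different lengths carry
    equal weight.
    """
    reps = [np.asarray(_stack(p), dtype=float).mean(axis=0) for p in paths]
    if not reps:
        raise ValueError("no paths supplied")
    return np.mean(reps, axis=0)


def roc_auc(pij: np.ndarray, true_adjacency: np.ndarray):
    """ROC by threshold sweep on the connection probabilities.

    Returns ``((fpr, tpr, thresholds), auc)`` with AUC computed by the
    trapezoid rule over all distinct thresholds.
    """
    scores = _upper(pij)
    labels = _upper(true_adjacency) != 0
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thr), auc


def _pooled_second_moment(data: LongitudinalDataset) -> np.ndarray:
    Y = data.pooled_values()
    return Y.T @ Y / Y.shape[0]


def baseline_glasso(data: LongitudinalDataset, lambdas, *,
                    penalize_diagonal: bool = False, glasso_tol: float = 1e-3,
                    glasso_max_iter: int = 100) -> SolutionPath:
    """Plain graphical lasso on pooled rows (longitudinal correlation ignored)."""
    S = _pooled_second_moment(data)
    n, p = data.n, data.p
    sign, ld = np.linalg.slogdet(S + 1e-12 * np.eye(p))
    fits = []
    for lam in np.asarray(lambdas, dtype=float):
        omega = glasso_subproblem(S, lam, penalize_diagonal=penalize_diagonal,
                                  tol=glasso_tol, max_iter=glasso_max_iter)
        s2, ldo = np.linalg.slogdet(omega)
        ll = 0.5 * n * (ldo - float(np.sum(S * omega)))
        fits.append(SGGMFit(
            omega=omega,
            dampening=DampeningModel(kind="homogeneous", tau=np.inf),
            lam=float(lam), loglik=float(ll),
            loglik_penalized=float(-2 * ll + n * penalty_value(omega, lam,
                                                               penalize_diagonal)),
            iterations=1, converged=True))
    return SolutionPath(fits=fits, lambdas=np.asarray(lambdas, float), n=n, p=p,
                        kind="glasso_baseline")


@dataclass
class NeighborhoodPath:
    """Per-node-lasso neighborhood selection along a penalty grid."""

    adjacencies: list[np.ndarray]
    lambdas: np.ndarray
    ebic: np.ndarray
    n: int
    p: int

    def adjacency_stack(self) -> np.ndarray:
        return np.stack(self.adjacencies)

    def select(self, T: float = 2.0):
        """Adjacency minimizing the regression-based EBIC (ties -> sparser)."""
        best = int(np.nonzero(self.ebic == self.ebic.min())[0][0])
        return self.adjacencies[best]


def baseline_neighborhood(data: LongitudinalDataset, lambdas, *, rule: str = "and",
                          ebic_T: float = 2.0) -> NeighborhoodPath:
    """Neighborhood (per-node lasso) selection on pooled rows.

    Each node is regressed on all others with an L1 penalty; an edge is
    kept where both (``and`` rule, default) or either (``or``) of the two
    directed coefficients is nonzero.  ``lambdas`` share the graphical
    lasso's penalty scale: each node's problem is
    ``(1/2)||y_j - X w||^2 + lam ||w||_1`` on the raw (unaveraged) sum of
    squares, so one grid serves all methods side by side.

    Model selection along the grid uses the pseudo-likelihood EBIC: the sum
    over nodes of the Gaussian profile deviance ``n log(RSS_j / n)`` of the
    lasso fit itself (no least-squares refit — the shrunken residuals keep
    the criterion honest when the pooled rows are strongly dependent), plus
    ``|G| (log n + log p / T)`` for the symmetrized edge set.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    Y = data.pooled_values()
    n, p = Y.shape
    lambdas = np.asarray(lambdas, dtype=float)
    adjacencies, ebics = [], []
    for lam in lambdas:
        coef = np.zeros((p, p))
        rss = np.empty(p)
        for j in range(p):
            others = np.delete(np.arange(p), j)
            model = Lasso(alpha=lam / n, fit_intercept=False, max_iter=2000)
            model.fit(Y[:, others], Y[:, j])
            coef[j, others] = model.coef_
            resid = Y[:, j] - Y[:, others] @ model.coef_
            rss[j] = float(resid @ resid)
        nz = coef != 0
        adj = (nz & nz.T) if rule == "and" else (nz | nz.T)
        adj = adj.astype(int)
        np.fill_diagonal(adj, 0)
        E = int(_upper(adj).sum())
        ebic = float(np.sum(n * np.log(np.maximum(rss, 1e-300) / n))
                     + E * (np.log(n) + np.log(p) / ebic_T))
        adjacencies.append(adj)
        ebics.append(ebic)
    return NeighborhoodPath(adjacencies=adjacencies, lambdas=lambdas,
                            ebic=np.asarray(ebics), n=n, p=p)
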