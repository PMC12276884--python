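"""Network–phylogeny concordance: ALR preprocessing, shortest-path
distance vectors, and the label-permutation significance test.

The scientific question: do taxa that are close in evolutionary history
also interact more in the estimated network?  Distances between taxa are
shortest-path hop counts — on the estimated interaction network, and on
the phylogenetic tree viewed as a graph (internal nodes traversed).  The
Pearson correlation ``r0`` between the two distance vectors, over taxon
pairs present in both structures and connected in the network, measures
concordance.  Significance is assessed by holding the network structure
fixed and permuting which taxon sits at which node: each permutation
yields a null correlation, and the one-sided p-value is
``(1 + #{r_perm >= r0}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .core import DataValidationError, LongitudinalDataset, SubjectBlock

__all__ = [
    "ALRResult",
    "DistanceVectors",
    "alr_transform",
    "network_distance_matrix",
    "tree_distance_matrix",
    "distance_vectors",
    "permutation_test",
    "PermutationTestResult",
]


@dataclass
class ALRResult:
    """Output of the additive log-ratio preprocessing."""

    dataset: LongitudinalDataset
    composite_taxa: list[str]
    reference: str = "composite"


def alr_transform(counts: pd.DataFrame, *, subject_col: str = "subject_id",
                  time_col: str = "time", rare_threshold: float = 0.10,
                  zero_divisor: float = 10.0, center: bool = True) -> ALRResult:
    """Additive log-ratio transform of a raw count table.

    ``counts`` holds one row per (subject, time) with taxon columns.  Taxa
    with a proportion of nonzero observations below ``rare_threshold`` are
    summed into a composite reference taxon; remaining zeros (including in
    the composite) are replaced by that column's minimum positive value
    divided by ``zero_divisor``; each taxon is then mapped to
    ``log(taxon / composite)``.  The composite is the reference only and is
    excluded from the returned taxa.  Output is centered per taxon unless
    ``center=False``.
    """
    taxa = [c for c in counts.columns if c not in (subject_col, time_col)]
    mat = counts[taxa].to_numpy(dtype=float)
    if np.any(mat < 0):
        raise DataValidationError("counts must be nonnegative")
    zero_cols = [t for t, col in zip(taxa, mat.T) if not np.any(col > 0)]
    if zero_cols:
        raise DataValidationError(f"taxa with no positive observations: {zero_cols}")
    nonzero_prop = (mat > 0).mean(axis=0)
    rare = nonzero_prop < rare_threshold
    if not np.any(rare):
        raise DataValidationError(
            "no taxon falls below the rarity threshold; an explicit reference "
            "taxon is required for the log-ratio transform")
    composite = mat[:, rare].sum(axis=1)
    keep = [t for t, r in zip(taxa, rare) if not r]
    kept = mat[:, ~rare]

    def fill_zeros(col: np.ndarray) -> np.ndarray:
        out = col.copy()
        if np.any(out == 0):
            out[out == 0] = out[out > 0].min() / zero_divisor
        return out

    kept = np.column_stack([fill_zeros(c) for c in kept.T])
    composite = fill_zeros(composite)
    logratio = np.log(kept / composite[:, None])
    if center:
        logratio = logratio - logratio.mean(axis=0)

    blocks = []
    for sid, grp_idx in counts.groupby(subject_col, sort=False).indices.items():
        idx = np.asarray(grp_idx)
        t = counts[time_col].to_numpy(dtype=float)[idx]
        order = np.argsort(t)
        blocks.append(SubjectBlock(str(sid), t[order], logratio[idx][order]))
    dataset = LongitudinalDataset(blocks, taxon_names=keep)
    return ALRResult(dataset=dataset, composite_taxa=[t for t, r in zip(taxa, rare) if r])


@dataclass
class DistanceVectors:
    """Paired shortest-path distances over common, network-connected pairs."""

    pair_index: list[tuple[str, str]]
    d1: np.ndarray  # network hop counts
    d2: np.ndarray  # tree hop counts (or branch-length sums)


def network_distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path hop counts (inf if disconnected)."""
    adj = (np.asarray(adjacency) != 0).astype(float)
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def tree_distance_matrix(tree: dendropy.Tree, taxa: list[str],
                         weighted: bool = False) -> np.ndarray:
    """Leaf-to-leaf distances on the tree treated as a graph.

    Hop counts traverse internal nodes; ``weighted=True`` sums branch
    lengths instead.
    """
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for nd in nodes:
        for ch in nd.child_nodes():
            w = ch.edge.length if (weighted and ch.edge.length is not None) else 1.0
            rows.append(index[id(nd)])
            cols.append(index[id(ch)])
            vals.append(float(w))
    g = csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    leaf_idx = {}
    for nd in tree.leaf_node_iter():
        if nd.taxon is not None:
            leaf_idx[nd.taxon.label] = index[id(nd)]
    missing = [t for t in taxa if t not in leaf_idx]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")
    sel = np.array([leaf_idx[t] for t in taxa])
    dist = shortest_path(g, method="D", directed=False,
                         unweighted=not weighted, indices=sel)
    return dist[:, sel]


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(path=str(tree), schema="newick",
                             preserve_underscores=True)


def distance_vectors(adjacency: np.ndarray, taxa: list[str], tree,
                     weighted_tree: bool = False) -> DistanceVectors:
    """Paired distance vectors for all taxon pairs common to both structures.

    Pairs disconnected in the network are dropped from both vectors (a tree
    is connected, so only network disconnection can trigger exclusion).
    """
    tree = _load_tree(tree)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    common = [t for t in taxa if t in labels]
    if not common:
        raise ValueError("network and tree share no taxa")
    pos = [taxa.index(t) for t in common]
    dnet = network_distance_matrix(adjacency)[np.ix_(pos, pos)]
    dtree = tree_distance_matrix(tree, common, weighted=weighted_tree)
    iu = np.triu_indices(len(common), k=1)
    d1, d2 = dnet[iu], dtree[iu]
    finite = np.isfinite(d1)
    pairs = [(common[i], common[j]) for i, j, ok in zip(*iu, finite) if ok]
    return DistanceVectors(pair_index=pairs, d1=d1[finite], d2=d2[finite])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return 0.0
    return float((xc @ yc) / den)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata
    return _pearson(rankdata(x), rankdata(y))


@dataclass
class PermutationTestResult:
    r0: float
    null_draws: np.ndarray
    p_value: float
    n_pairs: int
    n_perm: int


def permutation_test(adjacency: np.ndarray, taxa: list[str], tree, *,
                     n_perm: int = 5000, rng=None, method: str = "pearson",
                     weighted_tree: bool = False) -> PermutationTestResult:
    """Label-permutation test of network–tree concordance.

    The network structure is held fixed while the assignment of taxa to its
    nodes is permuted uniformly; each permutation rebuilds the network
    distance vector and recomputes the correlation against the fixed tree
    distances.  One-sided p-value with the add-one convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    corr = _pearson if method == "pearson" else _spearman
    tree = _load_tree(tree)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    common = [t for t in taxa if t in labels]
    if len(common) < 3:
        raise ValueError("need at least 3 shared taxa")
    pos = [taxa.index(t) for t in common]
    dnet = network_distance_matrix(adjacency)[np.ix_(pos, pos)]
    dtree = tree_distance_matrix(tree, common, weighted=weighted_tree)
    k = len(common)
    iu = np.triu_indices(k, 1)

    def corr_for(perm: np.ndarray) -> float:
        d1 = dnet[np.ix_(perm, perm)][iu]
        d2 = dtree[iu]
        finite = np.isfinite(d1)
        return corr(d1[finite], d2[finite])

    r0 = corr_for(np.arange(k))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = corr_for(rng.permutation(k))
    p = (1 + int(np.sum(null >= r0))) / (1 + n_perm)
    n_pairs = int(np.isfinite(dnet[iu]).sum())
    return PermutationTestResult(r0=r0, null_draws=null, p_value=p,
                                 n_pairs=n_pairs, n_perm=n_perm)
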