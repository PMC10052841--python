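"""Ordination (PCA, classical MDS) and neighbor-joining trees.

PCA operates on a centered, unscaled feature matrix — insertion dosages
for individual-level analysis, insertion frequencies for population-level
analysis — via SVD, with a deterministic sign convention (the first
nonzero entry of each loading vector is made non-negative).  Classical
(Torgerson) MDS double-centers the squared distance matrix and eigen-
decomposes it.  Neighbor joining follows Saitou & Nei with the
Studier-Keppler Q-criterion; ties in Q are broken by lexicographic
taxon-pair order so the output is independent of input ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import DistanceMatrix

__all__ = ["PcaResult", "pca", "genotype_pca", "frequency_pca",
           "classical_mds", "nj_tree"]


@dataclass
class PcaResult:
    coordinates: np.ndarray  # items x components
    explained_pct: np.ndarray
    loadings: np.ndarray  # features x components
    level: str  # "individual" | "population"


def pca(matrix: np.ndarray, n_components: int | None = None,
        level: str = "individual") -> PcaResult:
    """PCA of an items x features matrix (centered, unscaled).

    Missing entries are mean-imputed per feature before centering.
    Explained percentages are eigenvalue shares of total variance.
    """
    X = np.asarray(matrix, dtype=float).copy()
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    X -= X.mean(axis=0)
    total_var = (X**2).sum()
    if n_components is None:
        n_components = min(X.shape) if min(X.shape) < X.shape[0] else min(X.shape[0] - 1, X.shape[1])
    n_components = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    if total_var == 0.0:
        warnings.warn("constant matrix: all explained percentages are 0")
        return PcaResult(np.zeros((X.shape[0], n_components)),
                         np.zeros(n_components),
                         np.zeros((X.shape[1], n_components)), level)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: first nonzero loading entry non-negative
    for k in range(Vt.shape[0]):
        nz = np.flatnonzero(np.abs(Vt[k]) > 1e-12)
        if nz.size and Vt[k, nz[0]] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U[:, :n_components] * s[:n_components]
    pct = 100.0 * (s**2) / total_var
    return PcaResult(coords, pct[:n_components], Vt[:n_components].T, level)


def genotype_pca(g, n_components: int = 10) -> PcaResult:
    """Individual-level PCA on insertion dosages."""
    return pca(g.dosage, n_components, level="individual")


def frequency_pca(t, n_components: int = 10) -> PcaResult:
    """Population-level PCA on insertion-frequency profiles."""
    return pca(t.p_ins.T, n_components, level="population")


def classical_mds(d: DistanceMatrix, dims: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix.

    Coordinates for each positive eigenvalue are eigenvectors scaled by
    the square root of the eigenvalue; if fewer than ``dims`` positive
    eigenvalues exist the remaining columns are zero (with a warning).
    """
    D = d.values
    if (D < 0).any():
        raise ValueError("distances must be non-negative (clamp first)")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > 1e-12
    if pos.sum() < dims:
        warnings.warn(f"only {int(pos.sum())} positive eigenvalues; "
                      "padding coordinates with zeros")
    coords = np.zeros((n, dims))
    k = min(dims, int(pos.sum()))
    coords[:, :k] = V[:, :k] * np.sqrt(w[:k])
    return coords


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(d: DistanceMatrix, floor_negative: bool = True):
    """Neighbor-joining tree from a distance matrix (dendropy Tree).

    Standard Saitou-Nei agglomeration with the Studier-Keppler Q-matrix.
    The pair with minimal Q is joined; exact ties are broken by the
    lexicographically smallest (sorted) taxon-label pair, making the
    result invariant to input order.  Negative branch lengths are floored
    at 0 when ``floor_negative`` (MEGA convention); the tree is annotated
    with ``negative_branches_floored``.
    """
    import dendropy

    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n == 2:
        warnings.warn("2 taxa: returning a single-edge tree")
        for lab in labels:
            ch = tree.seed_node.new_child(edge_length=d.values[0, 1] / 2)
            ch.taxon = taxa.get_taxon(lab)
        tree.negative_branches_floored = False
        return tree

    nodes: dict[str, "dendropy.Node"] = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[lab] = node
    # active distance store keyed by frozenset of cluster names
    dist = {frozenset((a, b)): float(d.values[i, j])
            for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
    active = list(labels)
    floored = False
    next_id = 0

    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist[frozenset((a, b))] for b in active if b != a)
             for a in active}
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or key < best)):
                    best_q = q
                    best = key
        a, b = best
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if floor_negative and (la < 0 or lb < 0):
            floored = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        new_name = f"__internal_{next_id}"
        next_id += 1
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = la
        nb.edge.length = lb
        nodes[new_name] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab)
            dist[frozenset((new_name, c))] = duc
        active = [c for c in active if c not in (a, b)] + [new_name]

    a, b = sorted(active)
    dab = dist[frozenset((a, b))]
    if floor_negative and dab < 0:
        floored = True
        dab = 0.0
    na, nb = nodes[a], nodes[b]
    # attach the remaining cluster under the other to form the unrooted
    # tree's central edge (dendropy trees are rooted structures; seed at
    # the last internal node)
    root = nb if nb.is_internal() else na
    other = na if root is nb else nb
    root.add_child(other)
    other.edge.length = dab
    tree.seed_node = root
    tree.negative_branches_floored = floored
    tree.is_rooted = False
    return tree
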