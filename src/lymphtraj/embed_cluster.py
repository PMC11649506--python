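"""Normalization, PCA embedding, batch integration, Louvain clustering.

The embedding workflow mirrors the standard droplet pipeline: log-normalize
total counts, reduce to 50 principal components, correct the embedding for
sample-of-origin batch effects with an iterative soft-clustering linear
correction (Harmony-style), and cluster the corrected embedding with Louvain
modularity optimization (resolution 0.1) on a shared-nearest-neighbor graph
with 100 evaluated neighbors.

Two size-factor flavors are offered: plain library-size factors, and pooled
(deconvolution) factors estimated within Ward-linkage pre-clusters, which
are robust to strong composition differences between cell populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, ward
from scipy.sparse.linalg import lsqr
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from ._rng import substream

__all__ = [
    "Embedding",
    "lognormalize",
    "pca",
    "integrate",
    "louvain",
    "snn_graph",
    "modularity",
]


@dataclass
class Embedding:
    """Cells x components real embedding with explained variances."""

    cell_ids: np.ndarray
    coords: np.ndarray
    variances: np.ndarray
    batch_key: str | None = None
    corrected: bool = False

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def _as_dense(m) -> np.ndarray:
    return m.toarray() if sp.issparse(m) else np.asarray(m, dtype=float)


def _size_factors_libsize(totals: np.ndarray) -> np.ndarray:
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered before normalization")
    sf = totals / np.mean(totals)
    return sf


def _size_factors_pooled(X: np.ndarray, totals: np.ndarray, n_preclusters: int,
                         pool_sizes=(21, 25, 29, 33)) -> np.ndarray:
    """Deconvolved pool-based size factors within Ward pre-clusters.

    Cells are pre-clustered by Ward linkage on log library-size-normalized
    expression, then within each pre-cluster ring pools of cells give linear
    equations sum_{j in pool} sf_j = pool_size * median ratio(pooled profile,
    cluster reference); least squares recovers per-cell factors, which are
    finally rescaled so the global mean is 1.
    """
    n = X.shape[0]
    logn = np.log1p(X / totals[:, None] * np.median(totals))
    n_preclusters = min(n_preclusters, n)
    if n_preclusters > 1 and n > n_preclusters:
        Z = ward(logn)
        labels = fcluster(Z, t=n_preclusters, criterion="maxclust")
    else:
        labels = np.ones(n, dtype=int)
    sf = np.empty(n)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        m = len(idx)
        Xc = X[idx]
        ref = Xc.mean(axis=0)
        nz = ref > 0
        if m < min(pool_sizes):
            # too few cells to pool: fall back to median-ratio per cell
            with np.errstate(divide="ignore", invalid="ignore"):
                sf[idx] = [np.median(x[nz] / ref[nz]) for x in Xc]
            continue
        order = idx[np.argsort(totals[idx], kind="mergesort")]
        # alternate ends so ring neighbors have similar library sizes
        ring = np.empty(m, dtype=int)
        ring[0::2] = order[: (m + 1) // 2]
        ring[1::2] = order[(m + 1) // 2:][::-1]
        pos_in_cluster = {c: i for i, c in enumerate(ring)}
        rows, cols, vals, b = [], [], [], []
        eq = 0
        for size in pool_sizes:
            if size > m:
                continue
            for start in range(m):
                members = [ring[(start + k) % m] for k in range(size)]
                pooled = X[members].sum(axis=0)
                ratio = np.median(pooled[nz] / (size * ref[nz]))
                for c in members:
                    rows.append(eq)
                    cols.append(pos_in_cluster[c])
                    vals.append(1.0)
                b.append(size * ratio)
                eq += 1
        # low-weight anchor on the library-size factor keeps the system full rank
        for i, c in enumerate(ring):
            rows.append(eq)
            cols.append(i)
            vals.append(0.1)
            b.append(0.1 * totals[c] / np.mean(totals[idx]))
            eq += 1
        A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, m))
        sol = lsqr(A, np.asarray(b), atol=1e-10, btol=1e-10)[0]
        sf[ring] = np.clip(sol, 1e-8, None)
        # put the cluster on the common scale via its mean library size
        sf[idx] *= (totals[idx].mean() / np.mean(totals)) / np.mean(sf[idx])
    return sf / np.mean(sf)


def lognormalize(m, method: str = "libsize", scale: float = 1e4,
                 ward_preclusters: int = 5) -> np.ndarray:
    """Log-normalized expression, ``log1p(count / sizefactor / scale_ref)``.

    ``m`` is a CountMatrix (total layer used) or a cells x genes array.
    ``method='libsize'`` uses per-cell library-size factors; ``'pooled'``
    uses deconvolved pool-based factors within Ward pre-clusters.  With
    either method the counts of each cell are scaled to a common depth of
    ``scale`` before ``log1p``, and zero counts stay exactly zero.
    """
    X = _as_dense(m.layer("total")) if hasattr(m, "layer") else _as_dense(m)
    totals = X.sum(axis=1)
    if method == "libsize":
        sf = _size_factors_libsize(totals)
    elif method == "pooled":
        if np.any(totals <= 0):
            raise ValueError("cells with zero total counts must be filtered before normalization")
        sf = _size_factors_pooled(X, totals, ward_preclusters)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    eff = totals / sf  # effective common depth per cell
    return np.log1p(X / sf[:, None] * (scale / np.mean(eff)))


def size_factors(m, method: str = "libsize", ward_preclusters: int = 5) -> np.ndarray:
    X = _as_dense(m.layer("total")) if hasattr(m, "layer") else _as_dense(m)
    totals = X.sum(axis=1)
    if method == "libsize":
        return _size_factors_libsize(totals)
    return _size_factors_pooled(X, totals, ward_preclusters)


def pca(X, n: int = 50, center: bool = True, seed: int = 0, cell_ids=None) -> Embedding:
    """Principal-component scores via randomized SVD (10 power iterations).

    Scores match exact SVD of the centered matrix up to component sign;
    explained variances are non-increasing.  Requesting more components
    than the matrix rank returns the rank with a warning.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n_max = min(X.shape)
    if n > n_max:
        warnings.warn(f"n={n} exceeds min(cells, genes)={n_max}; truncating")
        n = n_max
    Xc = X - X.mean(axis=0) if center else X
    U, S, Vt = randomized_svd(
        Xc, n_components=n, n_iter=10, random_state=int(seed) % (2**31)
    )
    scores = U * S
    variances = S**2 / max(X.shape[0] - 1, 1)
    keep = variances > max(variances[0], 1.0) * 1e-12
    if keep.sum() < n:
        warnings.warn(f"rank {int(keep.sum())} < requested {n} components")
    if cell_ids is None:
        cell_ids = np.arange(X.shape[0])
    return Embedding(np.asarray(cell_ids), scores, variances)


def integrate(
    e: Embedding,
    batch,
    n_soft_clusters: int = 20,
    diversity_weight: float = 1.0,
    max_iter: int = 20,
    tol: float = 1e-4,
    sigma: float | None = None,
    seed: int = 0,
) -> Embedding:
    """Batch-effect correction of an embedding (Harmony-style).

    First matches the per-batch global centroids (removing any embedding-wide
    additive batch offset), then iterates soft k-means with a batch-diversity
    penalty and, per soft cluster, a per-batch linear centroid correction,
    until the change in soft assignments drops below ``tol`` or ``max_iter``
    is reached.  A single batch returns the input coordinates unchanged.
    """
    batch = np.asarray(batch)
    batches, b_codes = np.unique(batch, return_inverse=True)
    B = len(batches)
    if B == 1:
        return Embedding(e.cell_ids, e.coords.copy(), e.variances.copy(),
                         batch_key=e.batch_key, corrected=True)
    Z = e.coords.copy()
    n, d = Z.shape
    # global centering: align batch centroids before local refinement
    gmean = Z.mean(axis=0)
    for b in range(B):
        mask = b_codes == b
        Z[mask] -= Z[mask].mean(axis=0) - gmean
    K = min(n_soft_clusters, n // 2)
    rng_seed = int(substream(seed, "integrate").integers(2**31))
    frac_b = np.bincount(b_codes, minlength=B) / n

    km = KMeans(n_clusters=K, n_init=5, random_state=rng_seed).fit(Z)
    C = km.cluster_centers_
    R_prev = None
    for it in range(max_iter):
        d2 = (
            (Z**2).sum(axis=1)[:, None]
            - 2.0 * Z @ C.T
            + (C**2).sum(axis=1)[None, :]
        )
        bw = sigma if sigma is not None else max(float(np.mean(d2.min(axis=1))), 1e-12)
        logR = -d2 / (2.0 * bw)
        # diversity penalty: down-weight clusters where a cell's batch is
        # over-represented relative to the batch's global share
        R = np.exp(logR - logR.max(axis=1, keepdims=True))
        R /= R.sum(axis=1, keepdims=True)
        O = np.zeros((K, B))
        for b in range(B):
            O[:, b] = R[b_codes == b].sum(axis=0)
        E = O.sum(axis=1, keepdims=True) * frac_b[None, :]
        penalty = ((E + 1.0) / (O + 1.0)) ** diversity_weight
        R = R * penalty[:, b_codes].T
        R /= R.sum(axis=1, keepdims=True)

        if np.any(R.sum(axis=0) == 0):
            raise RuntimeError("empty soft cluster during integration")
        C = (R.T @ Z) / R.sum(axis=0)[:, None]

        # per-cluster, per-batch linear centroid correction
        correction = np.zeros_like(Z)
        for k in range(K):
            w = R[:, k]
            mu_k = (w @ Z) / max(w.sum(), 1e-12)
            for b in range(B):
                mask = b_codes == b
                wb = w[mask]
                sb = wb.sum()
                if sb < 1e-8:
                    continue
                mu_kb = (wb @ Z[mask]) / sb
                correction[mask] += np.outer(w[mask], mu_kb - mu_k)
        Z = Z - correction

        if R_prev is not None:
            delta = np.abs(R - R_prev).mean()
            if delta < tol:
                break
        R_prev = R
    return Embedding(e.cell_ids, Z, e.variances.copy(), batch_key=e.batch_key,
                     corrected=True)


def snn_graph(coords: np.ndarray, k_neighbors: int = 100, prune: float = 1 / 15):
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Edges connect kNN pairs; the weight is the Jaccard overlap of the two
    cells' neighbor lists (self included), pruned below ``prune``.
    Returns a symmetric sparse adjacency.
    """
    n = coords.shape[0]
    if n < k_neighbors + 1:
        raise ValueError("need more cells than k_neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    A = A.maximum(sp.eye(n, format="csr"))
    inter = (A @ A.T).tocoo()
    k_i = np.asarray(A.sum(axis=1)).ravel()
    union = k_i[inter.row] + k_i[inter.col] - inter.data
    jac = inter.data / union
    keep = (jac >= prune) & (inter.row != inter.col)
    W = sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    W = W.maximum(W.T)
    # keep only edges between actual kNN pairs
    mask = A.maximum(A.T)
    mask.data[:] = 1.0
    W = W.multiply(mask)
    return W.tocsr()


def modularity(adj: sp.spmatrix, labels, resolution: float = 1.0) -> float:
    """Resolution-scaled Newman modularity of a partition on a weighted graph."""
    A = sp.csr_matrix(adj)
    labels = np.asarray(labels)
    m2 = A.sum()  # sum over directed entries = 2m for symmetric A
    if m2 == 0:
        return 0.0
    deg = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += A[mask][:, mask].sum() / m2
        q -= resolution * (deg[mask].sum() / m2) ** 2
    return float(q)


def louvain(
    e,
    k_neighbors: int = 100,
    resolution: float = 0.1,
    seed: int = 0,
    adjacency: sp.spmatrix | None = None,
) -> np.ndarray:
    """Louvain community detection on the SNN graph of an embedding.

    ``e`` is an Embedding (or raw coordinate array); alternatively pass a
    prebuilt ``adjacency``.  Deterministic under a fixed seed.
    """
    import random as _random

    if adjacency is None:
        coords = e.coords if hasattr(e, "coords") else np.asarray(e, dtype=float)
        if coords.size == 0:
            raise ValueError("empty embedding")
        adjacency = snn_graph(coords, k_neighbors=k_neighbors)
    A = sp.coo_matrix(sp.triu(adjacency, k=0))
    g = ig.Graph(
        n=adjacency.shape[0],
        edges=list(zip(A.row.tolist(), A.col.tolist())),
        edge_attrs={"weight": A.data.tolist()},
    )
    ig.set_random_number_generator(_random.Random(int(seed)))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    ig.set_random_number_generator(_random)
    return np.asarray(part.membership)
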