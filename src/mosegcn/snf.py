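"""Similarity network fusion: per-omics patient graphs fused into one.

Each omics block yields a patient-by-patient affinity network via a scaled
exponential kernel on Euclidean distances, with a locally adaptive
bandwidth (the average distance to each point's K nearest neighbours).
Cross-diffusion then iteratively propagates each network's local (KNN)
structure through the average of the other networks, converging to a single
fused network that carries complementary evidence from every omics layer.
Weak edges are pruned before the fused network serves as the adjacency of
the graph classifier.

Defaults follow the original fusion algorithm's published settings:
K = 30 neighbours, kernel bandwidth multiplier mu = 0.5, T = 20 diffusion
iterations, diagonal weight 1/2 in the full kernel normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "AffinityNetwork",
    "FusedNetwork",
    "pairwise_distance",
    "affinity_kernel",
    "full_kernel",
    "local_affinity",
    "snf_fuse",
    "prune_weak_edges",
    "fused_to_edge_list",
    "edge_list_to_fused",
]


@dataclass(frozen=True)
class AffinityNetwork:
    """Symmetric non-negative patient similarity matrix for one omics."""

    W: np.ndarray
    name: str = ""
    k_neighbors: int = 30
    mu: float = 0.5

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.float64)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("affinity matrix must be square")
        if not np.isfinite(W).all():
            raise ValueError("affinity matrix has non-finite entries")
        if (W < 0).any():
            raise ValueError("affinity matrix has negative entries")
        if np.abs(W - W.T).max() > 1e-10:
            raise ValueError("affinity matrix is not symmetric within 1e-10")

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class FusedNetwork:
    """Output of cross-diffusion fusion (optionally pruned)."""

    matrix: np.ndarray
    iterations: int
    prune_rule: str = "none"
    prune_param: float | int | None = None

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", M)
        if np.abs(M - M.T).max() > 1e-8:
            raise ValueError("fused network not symmetric within 1e-8")
        if (M < 0).any():
            raise ValueError("fused network has negative entries")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def pairwise_distance(X: np.ndarray) -> np.ndarray:
    """Euclidean distance between sample rows; symmetric, zero diagonal."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    D = cdist(X, X, metric="euclidean")
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample rows (alternative metric)."""
    X = np.asarray(X, dtype=np.float64)
    D = cdist(X, X, metric="correlation")
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _knn_mean_distance(D: np.ndarray, k: int) -> np.ndarray:
    """Mean distance of each point to its k nearest neighbours (self excluded)."""
    n = D.shape[0]
    sorted_rows = np.sort(D, axis=1)[:, 1 : k + 1]  # drop the self zero
    return sorted_rows.mean(axis=1)


def affinity_kernel(
    D: np.ndarray, k_neighbors: int = 30, mu: float = 0.5, name: str = ""
) -> AffinityNetwork:
    """Scaled exponential kernel with locally adaptive bandwidth.

    W(i,j) = exp(-D(i,j)^2 / (mu * eps_ij)) with
    eps_ij = (mean kNN distance of i + mean kNN distance of j + D(i,j)) / 3.
    Coincident pairs (eps = 0) get affinity 1 by the exp(0) convention.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if k_neighbors >= n:
        warnings.warn(
            f"k_neighbors={k_neighbors} >= n_samples={n}; clamping to {n - 1}",
            stacklevel=2,
        )
        k_neighbors = n - 1
    mean_knn = _knn_mean_distance(D, k_neighbors)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(D**2) / (mu * eps))
    W[eps <= 0] = np.where(D[eps <= 0] == 0, 1.0, 0.0)
    W = (W + W.T) / 2.0
    return AffinityNetwork(W=W, name=name, k_neighbors=k_neighbors, mu=mu)


def full_kernel(W: np.ndarray) -> np.ndarray:
    """Full kernel normalisation: diagonal 1/2, off-diagonal rows sum to 1/2.

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) for j != i, P(i,i) = 1/2.
    """
    W = np.asarray(W, dtype=np.float64)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1, keepdims=True)
    if (row == 0).any():
        raise ValueError("isolated sample (all-zero affinity row)")
    P = off / (2.0 * row)
    np.fill_diagonal(P, 0.5)
    return P


def local_affinity(W: AffinityNetwork | np.ndarray, k_neighbors: int) -> np.ndarray:
    """Sparse KNN kernel S: row-normalised over each node's K nearest neighbours.

    S(i,j) = W(i,j) / sum_{k in KNN(i)} W(i,k) if j in KNN(i), else 0; the
    neighbourhood excludes i itself, so S has zero diagonal and rows that
    sum to 1.
    """
    Wm = W.W if isinstance(W, AffinityNetwork) else np.asarray(W, dtype=np.float64)
    n = Wm.shape[0]
    k_neighbors = min(k_neighbors, n - 1)
    S = np.zeros_like(Wm)
    for i in range(n):
        row = Wm[i].copy()
        row[i] = -np.inf  # exclude self
        nn = np.argsort(-row, kind="stable")[:k_neighbors]
        total = Wm[i, nn].sum()
        if total <= 0:
            raise ValueError(f"node {i} has no positive affinity to any neighbour")
        S[i, nn] = Wm[i, nn] / total
    return S


def snf_fuse(
    networks: list[AffinityNetwork],
    t_iterations: int = 20,
    k_neighbors: int | None = None,
) -> FusedNetwork:
    """Cross-diffusion fusion of two or more affinity networks.

    Each view's full kernel P_v is updated as
    P_v <- S_v x (mean of the other views' P) x S_v^T, then re-symmetrised
    and renormalised (full-kernel form) every iteration; the fused network
    is the mean of the final P_v. With identical inputs the update is
    numerically stationary, so fusion reduces to the normalised kernel.
    """
    if len(networks) < 2:
        raise ValueError("fusion needs at least two networks")
    n = networks[0].n_samples
    for net in networks[1:]:
        if net.n_samples != n:
            raise ValueError("all networks must cover the same samples")
    if k_neighbors is None:
        k_neighbors = networks[0].k_neighbors
    P = [full_kernel(net.W) for net in networks]
    S = [local_affinity(net, k_neighbors) for net in networks]
    m = len(networks)
    for _ in range(t_iterations):
        new_P = []
        for v in range(m):
            others = sum(P[w] for w in range(m) if w != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            Pv = (Pv + Pv.T) / 2.0
            new_P.append(full_kernel(Pv))
        P = new_P
    fused = sum(P) / m
    fused = (fused + fused.T) / 2.0
    return FusedNetwork(matrix=fused, iterations=t_iterations)


def prune_weak_edges(
    F: FusedNetwork,
    rule: str = "top-k",
    k_neighbors: int = 30,
    threshold: float = 0.0,
) -> FusedNetwork:
    """Zero out weak connections of the fused network.

    ``top-k`` (default): keep each node's K strongest off-diagonal edges,
    union-symmetrised — an edge survives if either endpoint retains it.
    ``threshold``: zero every off-diagonal entry strictly below the
    threshold. The diagonal is always preserved.
    """
    M = F.matrix.copy()
    n = M.shape[0]
    diag = M.diagonal().copy()
    if rule == "top-k":
        k = min(k_neighbors, n - 1)
        keep = np.zeros_like(M, dtype=bool)
        off = M.copy()
        np.fill_diagonal(off, -np.inf)
        for i in range(n):
            nn = np.argsort(-off[i], kind="stable")[:k]
            keep[i, nn] = True
        keep |= keep.T
        M = np.where(keep, M, 0.0)
        param: float | int = k
    elif rule == "threshold":
        M = np.where(M >= threshold, M, 0.0)
        param = threshold
    else:
        raise ValueError(f"unknown pruning rule {rule!r}")
    np.fill_diagonal(M, diag)
    M = (M + M.T) / 2.0
    return FusedNetwork(
        matrix=M, iterations=F.iterations, prune_rule=rule, prune_param=param
    )


# ------------------------------------------------------------------- export
def fused_to_edge_list(F: FusedNetwork, sample_ids: tuple[str, ...]) -> pd.DataFrame:
    """Upper-triangular nonzero entries as (sample_a, sample_b, weight)."""
    i, j = np.triu_indices(F.n_samples, k=1)
    w = F.matrix[i, j]
    nz = w > 0
    return pd.DataFrame(
        {
            "sample_a": [sample_ids[a] for a in i[nz]],
            "sample_b": [sample_ids[b] for b in j[nz]],
            "weight": w[nz],
        }
    )


def edge_list_to_fused(
    edges: pd.DataFrame, sample_ids: tuple[str, ...], diagonal: np.ndarray | None = None
) -> FusedNetwork:
    """Rebuild a fused network from an edge list (inverse of the export)."""
    pos = {s: i for i, s in enumerate(sample_ids)}
    n = len(sample_ids)
    M = np.zeros((n, n))
    for a, b, w in edges.itertuples(index=False):
        M[pos[a], pos[b]] = w
        M[pos[b], pos[a]] = w
    if diagonal is not None:
        np.fill_diagonal(M, diagonal)
    return FusedNetwork(matrix=M, iterations=0, prune_rule="imported")
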