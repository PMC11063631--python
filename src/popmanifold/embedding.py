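"""Two-round Laplacian-eigenmaps reduction of binned population activity.

Time bins are points in neuron space.  A binary mutual-kNN graph W is built
(edge iff each point is within the other's K nearest neighbors), and the
generalized eigenproblem L f = λ D f with L = D − W is solved; dropping the
constant leading eigenvector, the next m eigenvectors map each time bin to
m manifold coordinates.  Two rounds are used: neurons → 20 dims with
K = 7.5% of T, then 20 → 6 dims with K = 2.5% of T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from sklearn.neighbors import NearestNeighbors


@dataclass
class Embedding:
    coords: np.ndarray                       # T × m manifold coordinates
    stage_params: list[tuple[int, int, int]]  # (round, K, out_dim)
    graph: dict                              # adjacency summary per round
    stage_coords: list[np.ndarray] | None = None  # per-round coordinates


def knn_adjacency(points: np.ndarray, K: int) -> sp.csr_matrix:
    """Binary mutual-kNN adjacency (symmetric, zero diagonal).

    W_ij = 1 iff i is within j's K nearest neighbors and vice versa.
    Neighbor ties are resolved by index order.
    """
    points = np.asarray(points, dtype=float)
    T = points.shape[0]
    if not 1 <= K < T:
        raise ValueError(f"K must satisfy 1 <= K < T, got K={K}, T={T}")
    nn = NearestNeighbors(n_neighbors=K + 1).fit(points)
    graph = nn.kneighbors_graph(points, mode="connectivity")
    graph.setdiag(0)
    graph.eliminate_zeros()
    mutual = graph.multiply(graph.T)
    mutual = (mutual > 0).astype(float)
    return sp.csr_matrix(mutual)


def _repair_connectivity(
    W: sp.csr_matrix, points: np.ndarray
) -> tuple[sp.csr_matrix, int]:
    """Add Euclidean-MST edges so the graph becomes connected."""
    n_comp, _ = connected_components(W, directed=False)
    if n_comp == 1:
        return W, 0
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(points)).astype(np.float32)
    mst = minimum_spanning_tree(D)
    mst_sym = ((mst + mst.T) > 0).astype(float)
    W_new = ((W + mst_sym) > 0).astype(float)
    added = int((W_new.nnz - W.nnz) // 2)
    n_comp, labels = connected_components(W_new, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise RuntimeError(
            f"graph still disconnected after MST repair; component sizes {sizes.tolist()}"
        )
    return sp.csr_matrix(W_new), added


def laplacian_eigenmaps(
    points: np.ndarray,
    K: int,
    out_dim: int,
    repair: bool = True,
    return_info: bool = False,
):
    """Embed points by the first ``out_dim`` nontrivial Laplacian eigenvectors.

    Solves L f = λ D f via the symmetric normalization; eigenvectors are
    D-orthonormal and ordered by ascending eigenvalue, the constant leading
    one dropped.  Column signs are fixed (largest-magnitude entry positive)
    so the embedding is deterministic.
    """
    points = np.asarray(points, dtype=float)
    T = points.shape[0]
    if out_dim >= T - 1:
        raise ValueError("out_dim must be < T - 1")
    W = knn_adjacency(points, K)
    added = 0
    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        if not repair:
            sizes = np.bincount(labels)
            raise RuntimeError(
                f"mutual-kNN graph disconnected; component sizes {sizes.tolist()}"
            )
        W, added = _repair_connectivity(W, points)

    deg = np.asarray(W.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    # Lsym = I - D^-1/2 W D^-1/2 ; generalized eigvecs are f = D^-1/2 u
    Wn = W.multiply(inv_sqrt[:, None]).multiply(inv_sqrt[None, :])
    Lsym = sp.eye(T) - Wn
    dense = Lsym.toarray()
    dense = (dense + dense.T) / 2.0
    vals, vecs = eigh(dense, subset_by_index=[0, out_dim])
    f = vecs * inv_sqrt[:, None]
    # D-normalize: f' D f = u'u = 1 already; just fix signs deterministically
    coords = f[:, 1:]
    for j in range(coords.shape[1]):
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    if return_info:
        info = {
            "eigenvalues": vals,
            "edges": int(W.nnz // 2),
            "mst_edges_added": added,
            "connected": True,
        }
        return coords, info
    return coords


def round_k(T: int, frac: float) -> int:
    """K for one reduction round: nearest integer to frac·T, floor 2."""
    return max(2, int(round(frac * T)))


def two_round_reduce(
    z: np.ndarray,
    dims: tuple[int, int] = (20, 6),
    k_fracs: tuple[float, float] = (0.075, 0.025),
) -> Embedding:
    """Neuron × bin matrix → T × 6 manifold coordinates in two rounds."""
    z = np.asarray(z, dtype=float)
    points = z.T
    T = points.shape[0]
    if T < 200:
        raise ValueError(f"need at least 200 time bins, got {T}")
    stage_params = []
    graph_info = {}
    stage_coords = []
    for rnd, (m, frac) in enumerate(zip(dims, k_fracs), start=1):
        K = round_k(T, frac)
        points, info = laplacian_eigenmaps(points, K=K, out_dim=m, return_info=True)
        stage_params.append((rnd, K, m))
        graph_info[f"round{rnd}"] = info
        stage_coords.append(points)
    return Embedding(
        coords=points,
        stage_params=stage_params,
        graph=graph_info,
        stage_coords=stage_coords,
    )
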