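"""Manifold clustering with central-point-cloud exclusion.

Time points nearest the embedding centroid form a dense central cloud that
carries no cluster structure; the remaining points fall into peripheral
clusters.  The configuration — how many central points to exclude and the
K of K-means — is chosen on a grid: for every (n_excluded, K) cell the mean
per-point squared distance to the assigned centroid (MSE) over 20 K-means
repetitions is recorded, all three axes are scaled to [0, 1], and the cell
closest to the origin of that scaled 3-D system wins (few exclusions, few
clusters, low error).  Final labels are made deterministic by consensus:
500 seeded K-means runs at the optimal K, a co-association matrix over time
points, and Ward hierarchical clustering of that matrix cut at K groups.
Central-cloud points carry the sentinel label −1; clusters are 1..K*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans, MiniBatchKMeans


@dataclass
class ClusteringConfig:
    excluded_grid: np.ndarray
    k_grid: np.ndarray
    mse_grid: np.ndarray          # len(excluded) × len(k); NaN = invalid cell
    optimum: tuple[int, int]      # (n_excluded*, K*)


@dataclass
class ManifoldClustering:
    labels: np.ndarray            # per-bin label: -1 sentinel, 1..K_star
    K_star: int
    n_excluded: int
    config: ClusteringConfig | None = None
    rep_matrix: np.ndarray | None = field(default=None, repr=False)


def central_cloud_order(coords: np.ndarray) -> np.ndarray:
    """Bin indices sorted by ascending distance to the coordinate centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty embedding")
    dist = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    return np.argsort(dist, kind="stable")  # ties by bin index


def default_excluded_grid(T: int, start: int = 40, steps: int = 12) -> np.ndarray:
    """Geometric progression of central-cloud sizes from ``start`` toward T.

    The scan progresses to nearly the whole matrix (cells keep at least 40
    points so every K remains fittable).
    """
    stop = max(T - 2 * 20, start + 1)
    grid = np.unique(
        np.round(np.geomspace(start, stop, steps)).astype(int)
    )
    return grid[grid < T]


def _kmeans_mse(points: np.ndarray, k: int, seed: int, fast: bool) -> float:
    # within-cluster summed squared error (inertia): the error axis must
    # respond to the exclusion count, which a per-point mean would hide
    if fast:
        km = MiniBatchKMeans(
            n_clusters=k, n_init=1, random_state=seed, batch_size=1024,
            max_iter=100,
        )
    else:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    km.fit(points)
    return km.inertia_


def optimize_config(
    coords: np.ndarray,
    excluded_grid: np.ndarray | None = None,
    k_grid: np.ndarray | None = None,
    reps: int = 20,
    seed: int = 0,
) -> ClusteringConfig:
    """Grid search for the optimal (central-cloud size, K) configuration."""
    coords = np.asarray(coords, dtype=float)
    T = coords.shape[0]
    if excluded_grid is None:
        excluded_grid = default_excluded_grid(T)
    excluded_grid = np.asarray(excluded_grid, dtype=int)
    if k_grid is None:
        k_grid = np.arange(2, 21)
    k_grid = np.asarray(k_grid, dtype=int)
    if excluded_grid.size == 0 or k_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if excluded_grid.max() >= T:
        raise ValueError("max excluded count must be < T")

    order = central_cloud_order(coords)
    # mini-batch K-means keeps the scan tractable on long sessions; the
    # consensus stage always uses full Lloyd iterations
    fast = T > 3000
    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)

    mse = np.full((excluded_grid.size, k_grid.size), np.nan)
    for ei, n_exc in enumerate(excluded_grid):
        points = coords[order[n_exc:]]
        for ki, k in enumerate(k_grid):
            if points.shape[0] < k:
                continue  # invalid cell
            vals = [_kmeans_mse(points, int(k), int(s), fast) for s in seeds]
            mse[ei, ki] = float(np.mean(vals))

    if np.all(np.isnan(mse)):
        raise ValueError("no valid grid cell")

    def scale01(x):
        x = np.asarray(x, dtype=float)
        rng_ = x.max() - x.min()
        return (x - x.min()) / rng_ if rng_ > 0 else np.zeros_like(x)

    ex_s = scale01(excluded_grid)
    k_s = scale01(k_grid)
    valid = np.isfinite(mse)
    mse_s = np.full_like(mse, np.nan)
    mmin, mmax = np.nanmin(mse), np.nanmax(mse)
    mse_s[valid] = (mse[valid] - mmin) / (mmax - mmin) if mmax > mmin else 0.0

    dist2 = ex_s[:, None] ** 2 + k_s[None, :] ** 2 + mse_s**2
    dist2[~valid] = np.inf
    ei, ki = np.unravel_index(np.argmin(dist2), dist2.shape)
    return ClusteringConfig(
        excluded_grid=excluded_grid,
        k_grid=k_grid,
        mse_grid=mse,
        optimum=(int(excluded_grid[ei]), int(k_grid[ki])),
    )


def consensus_labels(
    coords: np.ndarray,
    config: ClusteringConfig,
    reps: int = 500,
    seed: int = 0,
    linkage: str = "ward",
    keep_rep_matrix: bool = False,
) -> ManifoldClustering:
    """Deterministic consensus labels at the optimal configuration.

    The co-association matrix (fraction of K-means repetitions assigning two
    time points together) makes the consensus invariant to per-repetition
    label permutations; Ward (default) or complete linkage on its complement
    cut at K* groups yields the final labels.
    """
    coords = np.asarray(coords, dtype=float)
    n_excluded, k_star = config.optimum
    order = central_cloud_order(coords)
    central = order[:n_excluded]
    periph = order[n_excluded:]
    points = coords[periph]
    n = points.shape[0]

    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    rep_matrix = np.empty((reps, n), dtype=np.int16)
    coassoc = np.zeros((n, n), dtype=np.float32)
    for r, s in enumerate(seeds):
        lab = KMeans(n_clusters=k_star, n_init=1, random_state=int(s)).fit_predict(
            points
        )
        rep_matrix[r] = lab
        coassoc += lab[:, None] == lab[None, :]
    coassoc /= reps

    dist = 1.0 - coassoc
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist.astype(np.float64), checks=False)
    Z = sch.linkage(condensed, method=linkage)
    groups = sch.fcluster(Z, t=k_star, criterion="maxclust")

    labels = np.full(coords.shape[0], -1, dtype=int)
    labels[periph] = groups
    return ManifoldClustering(
        labels=labels,
        K_star=k_star,
        n_excluded=n_excluded,
        config=config,
        rep_matrix=rep_matrix if keep_rep_matrix else None,
    )
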