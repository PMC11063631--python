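"""Topological comparison of activity manifolds.

The embedded point cloud is condensed to 80 K-means landmarks (20 stochastic
repetitions), Vietoris–Rips persistent homology is computed in degrees 0
(components) and 1 (loops), and each feature contributes its lifespan
(death − birth radius).  Two datasets are compared by the mean 1-D
Wasserstein distance between their lifespan distributions over all
repetition pairs; significance comes from a pooled-resplit permutation test
in which the p-value is the fraction of permuted distances *below* the
observed one — small p is evidence that the shapes differ more than chance,
i.e. the test is one of similarity as much as difference.

Rips persistence is computed in-package: degree 0 by Kruskal union-find
(deaths are the component-merging edge weights), degree 1 by GF(2) boundary
reduction of the triangle columns (the clearing shortcut: the pivots of the
reduced ∂₂ are exactly the cycle-creating edges).  The filtration is capped
at the landmark-set diameter, at which the 2-skeleton is complete and every
loop has died, so all degree-1 lifespans are finite; the single infinite
degree-0 feature is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import wasserstein_distance
from sklearn.cluster import KMeans


@dataclass
class LifespanDistribution:
    degree: int
    lifespans: list[np.ndarray]   # one array per clustering repetition
    landmark_k: int = 80

    def pooled(self) -> np.ndarray:
        return np.concatenate([ls for ls in self.lifespans]) if self.lifespans else np.array([])


@dataclass
class TopoComparison:
    distance: float
    p_value: float
    n_perm: int


# ---------------------------------------------------------------- landmarks

def condense_landmarks(
    coords: np.ndarray, k: int = 80, reps: int = 20, seed: int = 0
) -> list[np.ndarray]:
    """K-means centroid sets (one per repetition, random init per rep)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] <= k:
        raise ValueError(f"need more than {k} points, got {coords.shape[0]}")
    seeds = np.random.SeedSequence(seed).generate_state(reps)
    out = []
    for s in seeds:
        km = KMeans(n_clusters=k, n_init=1, random_state=int(s % (2**31)))
        km.fit(coords)
        out.append(km.cluster_centers_.copy())
    return out


# ---------------------------------------------------- Rips persistence core

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def rips_lifespans(points: np.ndarray) -> dict[int, np.ndarray]:
    """Vietoris–Rips lifespans in degrees 0 and 1 for a small point set.

    All births in degree 0 are at radius 0, so each degree-0 lifespan equals
    the death radius of a component.  Degree-1 features are (cycle edge,
    filling triangle) persistence pairs; zero-lifespan pairs are dropped.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    d = pdist(points)
    if np.all(d == 0):
        raise ValueError("degenerate input: all points identical")

    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    order = np.argsort(d, kind="stable")
    w_sorted = d[order]
    pairs_sorted = pairs[order]

    # ---- degree 0: Kruskal union-find; merge weights are death radii
    uf = _UnionFind(n)
    h0 = []
    for w, (i, j) in zip(w_sorted, pairs_sorted):
        if uf.union(int(i), int(j)):
            h0.append(w)
    h0 = np.asarray(h0)  # n-1 finite deaths; the last component is infinite

    # ---- degree 1: reduce triangle boundary columns over GF(2)
    # edge index in filtration order
    edge_rank = {}
    for r, (i, j) in enumerate(pairs_sorted):
        edge_rank[(int(i), int(j))] = r

    # triangles with filtration value = max edge weight
    tri_filt = []
    tri_edges = []
    for a in range(n):
        for b in range(a + 1, n):
            rab = edge_rank[(a, b)]
            for c in range(b + 1, n):
                rac = edge_rank[(a, c)]
                rbc = edge_rank[(b, c)]
                rmax = max(rab, rac, rbc)
                tri_filt.append(rmax)           # filtration order by latest edge
                tri_edges.append((rab, rac, rbc))
    tri_order = np.argsort(np.asarray(tri_filt), kind="stable")

    pivot: dict[int, frozenset] = {}
    h1 = []
    for t in tri_order:
        col = frozenset(tri_edges[t])
        low = max(col)
        while col and low in pivot:
            col = col ^ pivot[low]
            if col:
                low = max(col)
        if col:
            pivot[low] = col
            birth = w_sorted[low]
            death = w_sorted[tri_filt[t]]
            if death > birth:
                h1.append(death - birth)
    return {0: h0, 1: np.asarray(sorted(h1, reverse=True))}


def compute_lifespans(
    landmark_sets: list[np.ndarray] | np.ndarray, landmark_k: int | None = None
) -> dict[int, LifespanDistribution]:
    """Lifespan distributions per homology degree over landmark repetitions."""
    if isinstance(landmark_sets, np.ndarray) and landmark_sets.ndim == 2:
        landmark_sets = [landmark_sets]
    per_degree: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for pts in landmark_sets:
        res = rips_lifespans(pts)
        per_degree[0].append(res[0])
        per_degree[1].append(res[1])
    k = landmark_k if landmark_k is not None else landmark_sets[0].shape[0]
    return {
        deg: LifespanDistribution(degree=deg, lifespans=ls, landmark_k=k)
        for deg, ls in per_degree.items()
    }


# ------------------------------------------------------------- comparisons

def wasserstein_similarity(
    a: LifespanDistribution, b: LifespanDistribution
) -> float:
    """Mean 1-D Wasserstein distance over all repetition pairings."""
    if a.degree != b.degree:
        raise ValueError("lifespan distributions have different degrees")
    if not a.lifespans or not b.lifespans:
        raise ValueError("empty lifespan distribution")
    dists = []
    for la in a.lifespans:
        for lb in b.lifespans:
            if la.size == 0 or lb.size == 0:
                raise ValueError("empty lifespan list in a repetition")
            dists.append(wasserstein_distance(la, lb))
    return float(np.mean(dists))


def permutation_test(
    a: LifespanDistribution,
    b: LifespanDistribution,
    n_perm: int = 200,
    seed: int = 0,
) -> TopoComparison:
    """Pooled-resplit permutation test, averaged over clustering repetitions.

    Per repetition r the observed distance is W1(a_r, b_r); the two lifespan
    lists are pooled, re-split at their original sizes n_perm times, and
    p_r = fraction of permuted distances strictly below the observed one.
    The returned p-value is the mean of the per-repetition p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(a.lifespans) != len(b.lifespans):
        raise ValueError("repetition counts differ")
    rng = np.random.default_rng(seed)
    p_values = []
    observed = []
    for la, lb in zip(a.lifespans, b.lifespans):
        pooled = np.concatenate([la, lb])
        if pooled.size < 4:
            raise ValueError("need at least 4 pooled lifespans")
        obs = wasserstein_distance(la, lb)
        observed.append(obs)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if wasserstein_distance(perm[: la.size], perm[la.size:]) < obs:
                count += 1
        p_values.append(count / n_perm)
    return TopoComparison(
        distance=float(np.mean(observed)),
        p_value=float(np.mean(p_values)),
        n_perm=n_perm,
    )
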