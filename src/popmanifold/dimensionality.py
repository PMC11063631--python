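"""Intrinsic-dimension estimation from nearest-neighbor distance ratios.

For each point the ratio of its second-nearest to nearest neighbor distance
μ = r2/r1 follows, on a locally uniform d-dimensional manifold, a Pareto law
with shape parameter d.  The estimator regresses −log(1 − F(μ)) on log μ
through the origin, after discarding the largest 4% of ratios (boundary and
outlier points distort the Pareto tail).  The literature sometimes prints the
inverted ratio r1/r2; we use the r2/r1 ≥ 1 orientation so the regression
slope is directly the dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class DimEstimate:
    d_hat: float
    mu: np.ndarray           # per-point ratio r2/r1 (>= 1)
    F: np.ndarray            # empirical percentile of mu, rank/(n+1)
    n_used: int              # points retained after tail exclusion
    fit: dict                # regression diagnostics
    profile: list[tuple[int, float]] | None = None  # (dim, estimate) stages


def estimate_dimension(
    points: np.ndarray, discard_top_frac: float = 0.04
) -> DimEstimate:
    """TWO-NN intrinsic dimension of a T × D point set.

    Raises on duplicate points (the nearest-neighbor distance must be
    positive) and on T < 50 (the tail regression is unstable below that).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < 50:
        raise ValueError(f"need at least 50 points, got {n}")
    nn = NearestNeighbors(n_neighbors=3).fit(points)
    dists, _ = nn.kneighbors(points)
    r1, r2 = dists[:, 1], dists[:, 2]
    dup = np.flatnonzero(r1 == 0)
    if dup.size:
        raise ValueError(f"duplicate points at indices {dup.tolist()[:10]}")
    mu = r2 / r1

    order = np.argsort(mu, kind="stable")
    mu_sorted = mu[order]
    F = (np.arange(1, n + 1)) / (n + 1)  # rank/(n+1) avoids log(0)
    n_keep = n - int(np.floor(discard_top_frac * n))
    x = np.log(mu_sorted[:n_keep])
    y = -np.log1p(-F[:n_keep])
    # least squares through the origin
    sxx = float(np.dot(x, x))
    d_hat = float(np.dot(x, y) / sxx)
    resid = y - d_hat * x
    fit = {
        "sxx": sxx,
        "rss": float(np.dot(resid, resid)),
        "n_points": n,
    }
    return DimEstimate(d_hat=d_hat, mu=mu, F=F, n_used=n_keep, fit=fit)


def estimate_dimension_iterative(
    z: np.ndarray,
    intermediate_dims: list[int],
    k_frac: float = 0.075,
    discard_top_frac: float = 0.04,
) -> DimEstimate:
    """Estimate dimension across denoising spectral reductions.

    ``z`` is a neuron × bin matrix; time bins are the points.  The estimate is
    computed on the raw matrix and after a Laplacian-eigenmaps reduction to
    each dim in ``intermediate_dims`` (descending).  A correct estimate is
    invariant to the embedding dimension, so the reported value is taken at
    the plateau: the smallest intermediate dim whose estimate lies within 1
    of the previous stage's.
    """
    from .embedding import laplacian_eigenmaps

    z = np.asarray(z, dtype=float)
    dims = list(intermediate_dims)
    if dims != sorted(dims, reverse=True):
        raise ValueError("intermediate_dims must be descending")
    if any(d >= z.shape[0] for d in dims if d != z.shape[0]):
        # allow dims == n_neurons meaning "no reduction"
        pass
    points = z.T
    T = points.shape[0]
    K = max(2, int(round(k_frac * T)))

    est_raw = estimate_dimension(points, discard_top_frac)
    profile: list[tuple[int, float]] = [(points.shape[1], est_raw.d_hat)]
    stage_results: dict[int, DimEstimate] = {points.shape[1]: est_raw}
    for m in dims:
        if m >= points.shape[1]:  # no reduction requested
            profile.append((m, est_raw.d_hat))
            stage_results[m] = est_raw
            continue
        reduced = laplacian_eigenmaps(points, K=K, out_dim=m)
        # the reduction can collapse near-identical bins onto one point;
        # duplicates carry no neighbor-ratio information (rounding well below
        # the coordinate scale also merges pairs whose computed distance
        # underflows to zero)
        reduced = np.unique(np.round(reduced, 9), axis=0)
        est = estimate_dimension(reduced, discard_top_frac)
        profile.append((m, est.d_hat))
        stage_results[m] = est

    # plateau: smallest dim whose estimate is within 1 of the previous stage
    chosen_dim = profile[-1][0]
    for prev, cur in zip(profile[:-1], profile[1:]):
        if abs(cur[1] - prev[1]) <= 1.0:
            chosen_dim = cur[0]
    result = stage_results[chosen_dim]
    result.profile = profile
    return result


def subsample_control(
    pointsets: list[np.ndarray],
    n_target: int,
    reps: int = 10,
    seed: int = 0,
    discard_top_frac: float = 0.04,
) -> list[dict]:
    """Neuron-subsampling control for cross-session dimension comparison.

    Each element of ``pointsets`` is a neuron × bin matrix.  For every
    session, ``reps`` random subsets of ``n_target`` neurons are drawn and the
    dimension estimated on each; returns per-session mean ± SD so sessions
    with different neuron counts can be compared fairly.
    """
    if n_target < 3:
        raise ValueError("n_target must be >= 3")
    for z in pointsets:
        if n_target > z.shape[0]:
            raise ValueError("n_target exceeds a session's neuron count")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for z in pointsets:
        estimates = []
        for _ in range(reps):
            idx = rng.choice(z.shape[0], size=n_target, replace=False)
            estimates.append(
                estimate_dimension(z[idx].T, discard_top_frac).d_hat
            )
        estimates = np.asarray(estimates)
        out.append(
            {
                "mean": float(estimates.mean()),
                "sd": float(estimates.std()),
                "estimates": estimates,
            }
        )
    return out
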